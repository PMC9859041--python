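{
  "_comment": "Synthetic V-gene germline CDR1/CDR2/CDR2.5 loop table for the gene names used by the fixture generator and tests. Mirrors the layout of germline lookup tables; not real germline sequences.",
  "alpha": {
    "TRAV-SYN1*01": {"cdr1": "TSGFYG", "cdr2": "NALDGL", "cdr25": "SVKG"},
    "TRAV-SYN2*01": {"cdr1": "DSAIYN", "cdr2": "IQSSQRE", "cdr25": "TLHG"},
    "TRAV-SYN3*01": {"cdr1": "NSAFQY", "cdr2": "TYSSGN", "cdr25": "MARG"},
    "TRAV-SYN4*01": {"cdr1": "VSGNPY", "cdr2": "YITGDNLV", "cdr25": "KESG"}
  },
  "beta": {
    "TRBV-SYN1*01": {"cdr1": "SGHRS", "cdr2": "YFSETQ", "cdr25": "ADKG"},
    "TRBV-SYN2*01": {"cdr1": "MNHEY", "cdr2": "SVGAGI", "cdr25": "TDQG"},
    "TRBV-SYN3*01": {"cdr1": "SGHAT", "cdr2": "FQNNGV", "cdr25": "SEGG"},
    "TRBV-SYN4*01": {"cdr1": "LGHNA", "cdr2": "YSLEER", "cdr25": "VNDG"}
  }
}
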