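{
  "_comment": "Synthetic reference core profiles. Sequences and core indices describe the idealized fixture complexes generated by tcrpmhc.synthetic; they are stand-ins for crystallographic reference tables and can be replaced without code changes.",
  "1": {
    "mhc_sequence": "CSQKKVCQFCMYRSRSMDTLMIEWSPKTMKLFCNVCVTGPESRICYKV",
    "mhc_n_half": [6, 8, 10, 12, 14, 16],
    "mhc_c_half": [30, 32, 34, 36, 38, 40],
    "tcra_sequence": "GQSVTQTSGFYGWYRQDPNALDGLKGLTSVKGDRFSVECAVSDLEPNSSYKFGKGT",
    "tcra_core": [1, 2, 3, 4, 13, 14, 15, 16, 33, 34, 35, 52, 53],
    "tcrb_sequence": "DAGVTQSGHRSWYRQDTYFSETQKGEVADKGNRFSAECASSIRSSYEQYFFGEGS",
    "tcrb_core": [1, 2, 3, 4, 12, 13, 14, 15, 32, 33, 34, 51, 52]
  },
  "2": {
    "mhc_sequence": "QSSEILLAMERQWRIYKHWICLSELDQLHFNQWKETPRCHSTKTTIVG",
    "mhc_n_half": [6, 8, 10, 12, 14, 16],
    "mhc_c_half": [30, 32, 34, 36, 38, 40],
    "tcra_sequence": "GQSVTQTSGFYGWYRQDPNALDGLKGLTSVKGDRFSVECAVSDLEPNSSYKFGKGT",
    "tcra_core": [1, 2, 3, 4, 13, 14, 15, 16, 33, 34, 35, 52, 53],
    "tcrb_sequence": "DAGVTQSGHRSWYRQDTYFSETQKGEVADKGNRFSAECASSIRSSYEQYFFGEGS",
    "tcrb_core": [1, 2, 3, 4, 12, 13, 14, 15, 32, 33, 34, 51, 52]
  }
}
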