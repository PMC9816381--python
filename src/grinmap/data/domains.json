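{
 "note": "Approximate reconstruction of GluN subunit topological-domain ranges (canonical UniProt numbering, signal peptide included). Sublobe split ATD1/ATD2; LBD = S1+S2 (317 positions per subunit); TMD = M1-M3 + M4 (140 positions per subunit). Edit to match a curated OPM-derived definition before analysing real structures.",
 "domains": [
  {"subunit": "GluN1",  "domain": "ATD1", "ranges": [[19, 208]]},
  {"subunit": "GluN1",  "domain": "ATD2", "ranges": [[209, 418]]},
  {"subunit": "GluN1",  "domain": "LBD",  "ranges": [[419, 550], [657, 841]]},
  {"subunit": "GluN1",  "domain": "TMD",  "ranges": [[551, 656], [842, 875]]},
  {"subunit": "GluN2A", "domain": "ATD1", "ranges": [[20, 209]]},
  {"subunit": "GluN2A", "domain": "ATD2", "ranges": [[210, 419]]},
  {"subunit": "GluN2A", "domain": "LBD",  "ranges": [[420, 551], [658, 842]]},
  {"subunit": "GluN2A", "domain": "TMD",  "ranges": [[552, 657], [843, 876]]},
  {"subunit": "GluN2B", "domain": "ATD1", "ranges": [[21, 210]]},
  {"subunit": "GluN2B", "domain": "ATD2", "ranges": [[211, 420]]},
  {"subunit": "GluN2B", "domain": "LBD",  "ranges": [[421, 552], [659, 843]]},
  {"subunit": "GluN2B", "domain": "TMD",  "ranges": [[553, 658], [844, 877]]}
 ]
}
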