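phase,category,mean_charge,sd_charge
preoperative,Clinic,339,163
preoperative,Ancillary,164,89
preoperative,Diagnostic,1578,1061
perioperative,Ancillary,113,378
perioperative,Diagnostic,944,359
perioperative,Gen nursing,6498,1444
perioperative,Minimally invasive procedures,13,41
perioperative,Pharmacy,3002,520
perioperative,Surgery and procedures,29036,2547
foundation,Surgical foundation,3312,552
postoperative,Clinic,633,619
postoperative,Ancillary,1630,1134
postoperative,Surgery and procedures,175,584
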