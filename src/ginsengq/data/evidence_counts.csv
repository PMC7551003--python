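# Published counts of ginseng literature records by benefit category and study
# subject: three Panax ginseng processing variants (whole-extract studies) and
# twelve individually studied ginsenosides. Transcribed from the printed
# summary table of a published systematic literature survey.
function,white,red,black,Rg1,Re,Rf,Rb1,Rc,Rb2,Rd,Rg2,Rh1,Rg3,Rk1,Rg5
Enhanced Immunity,48,37,3,18,11,1,15,2,2,10,0,5,5,2,4
Fatigue Relief,6,9,8,0,0,0,3,0,0,1,0,0,5,0,0
Enhanced Blood Flow,2,20,1,4,0,0,0,0,0,1,2,0,3,0,0
Enhanced Memory,16,4,7,9,1,0,9,0,0,2,1,2,1,0,1
Antioxidant,9,29,8,6,5,0,1,0,1,6,1,1,12,2,3
Antidepressant/Antianxiety,9,2,0,4,1,0,3,0,0,0,0,0,0,0,0
Decreased Body Fat,5,15,3,4,3,0,5,2,2,1,0,1,2,0,0
Decreased Blood Pressure,18,16,1,3,0,0,4,0,0,2,0,1,5,0,0
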