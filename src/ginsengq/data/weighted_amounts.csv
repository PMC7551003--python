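# Published literature-weighted average ginsenoside amounts (weight x mg/g)
# per benefit category for black (BG) and red (RG) ginseng, transcribed cell
# by cell from the printed comparison table of a published systematic
# literature survey. "Total" rows are the printed column totals and carry the
# table's printed rounding; absent ("-") cells are omitted.
function,variant,compound,weighted_mg_per_g
Enhanced Immunity,black,Rb1,7.69
Enhanced Immunity,red,Rb1,20.36
Enhanced Immunity,black,Rb2,1.06
Enhanced Immunity,red,Rb2,3.19
Enhanced Immunity,black,Rc,2.69
Enhanced Immunity,red,Rc,8.89
Enhanced Immunity,black,Rd,1.57
Enhanced Immunity,red,Rd,5.76
Enhanced Immunity,black,Re,0.95
Enhanced Immunity,red,Re,8.20
Enhanced Immunity,black,Rf,2.38
Enhanced Immunity,red,Rf,4.61
Enhanced Immunity,black,Rg1,2.19
Enhanced Immunity,red,Rg1,9.34
Enhanced Immunity,black,Rg3,24.73
Enhanced Immunity,red,Rg3,3.39
Enhanced Immunity,black,Rg5,5.69
Enhanced Immunity,red,Rg5,0.32
Enhanced Immunity,black,Rh1,1.56
Enhanced Immunity,red,Rh1,2.45
Enhanced Immunity,black,Rk1,2.12
Enhanced Immunity,red,Rk1,0.06
Enhanced Immunity,black,Total,52.68
Enhanced Immunity,red,Total,66.61
Fatigue Relief,black,Rb1,6.30
Fatigue Relief,red,Rb1,16.68
Fatigue Relief,black,Rd,1.59
Fatigue Relief,red,Rd,5.82
Fatigue Relief,black,Rg3,13.82
Fatigue Relief,red,Rg3,1.90
Fatigue Relief,black,Total,21.72
Fatigue Relief,red,Total,24.40
Enhanced Blood Flow,black,Rd,1.19
Enhanced Blood Flow,red,Rd,4.36
Enhanced Blood Flow,black,Rg1,0.70
Enhanced Blood Flow,red,Rg1,3.00
Enhanced Blood Flow,black,Rg2,1.77
Enhanced Blood Flow,red,Rg2,0.54
Enhanced Blood Flow,black,Rg3,11.13
Enhanced Blood Flow,red,Rg3,1.53
Enhanced Blood Flow,black,Rk1,3.06
Enhanced Blood Flow,red,Rk1,0.08
Enhanced Blood Flow,black,Total,17.87
Enhanced Blood Flow,red,Total,9.54
Enhanced Memory,black,Rb1,2.73
Enhanced Memory,red,Rb1,7.22
Enhanced Memory,black,Rd,0.39
Enhanced Memory,red,Rd,1.45
Enhanced Memory,black,Re,0.25
Enhanced Memory,red,Re,2.15
Enhanced Memory,black,Rg1,0.80
Enhanced Memory,red,Rg1,3.42
Enhanced Memory,black,Rg2,0.68
Enhanced Memory,red,Rg2,0.21
Enhanced Memory,black,Rg3,9.74
Enhanced Memory,red,Rg3,1.33
Enhanced Memory,black,Rg5,11.40
Enhanced Memory,red,Rg5,0.64
Enhanced Memory,black,Rh1,0.72
Enhanced Memory,red,Rh1,1.12
Enhanced Memory,black,Total,26.73
Enhanced Memory,red,Total,17.58
Antioxidant,black,Rb1,1.97
Antioxidant,red,Rb1,5.22
Antioxidant,black,Rb2,0.78
Antioxidant,red,Rb2,2.34
Antioxidant,black,Rd,2.20
Antioxidant,red,Rd,8.07
Antioxidant,black,Re,0.32
Antioxidant,red,Re,2.82
Antioxidant,black,Rg1,1.70
Antioxidant,red,Rg1,7.26
Antioxidant,black,Rg2,2.75
Antioxidant,red,Rg2,0.85
Antioxidant,black,Rg3,13.90
Antioxidant,red,Rg3,1.91
Antioxidant,black,Rg5,2.33
Antioxidant,red,Rg5,0.13
Antioxidant,black,Rh1,1.41
Antioxidant,red,Rh1,2.21
Antioxidant,black,Rk1,2.12
Antioxidant,red,Rk1,0.06
Antioxidant,black,Total,29.53
Antioxidant,red,Total,30.89
Antidepressant/Antianxiety,black,Rb1,3.23
Antidepressant/Antianxiety,red,Rb1,8.55
Antidepressant/Antianxiety,black,Re,1.00
Antidepressant/Antianxiety,red,Re,8.62
Antidepressant/Antianxiety,black,Rg1,1.07
Antidepressant/Antianxiety,red,Rg1,4.59
Antidepressant/Antianxiety,black,Total,5.32
Antidepressant/Antianxiety,red,Total,21.77
Decreased Body Fat,black,Rb1,10.00
Decreased Body Fat,red,Rb1,26.46
Decreased Body Fat,black,Rb2,1.21
Decreased Body Fat,red,Rb2,3.65
Decreased Body Fat,black,Rc,1.30
Decreased Body Fat,red,Rc,4.31
Decreased Body Fat,black,Rd,0.79
Decreased Body Fat,red,Rd,2.91
Decreased Body Fat,black,Re,0.46
Decreased Body Fat,red,Re,3.96
Decreased Body Fat,black,Rg1,1.79
Decreased Body Fat,red,Rg1,7.64
Decreased Body Fat,black,Rg3,9.43
Decreased Body Fat,red,Rg3,1.29
Decreased Body Fat,black,Rh1,0.70
Decreased Body Fat,red,Rh1,1.10
Decreased Body Fat,black,Total,25.72
Decreased Body Fat,red,Total,51.36
Decreased Blood Pressure,black,Rb1,2.55
Decreased Blood Pressure,red,Rb1,6.75
Decreased Blood Pressure,black,Rd,0.39
Decreased Blood Pressure,red,Rd,1.45
Decreased Blood Pressure,black,Rg1,2.02
Decreased Blood Pressure,red,Rg1,8.62
Decreased Blood Pressure,black,Rg3,7.97
Decreased Blood Pressure,red,Rg3,1.09
Decreased Blood Pressure,black,Rh1,0.70
Decreased Blood Pressure,red,Rh1,1.10
Decreased Blood Pressure,black,Total,13.65
Decreased Blood Pressure,red,Total,19.03
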