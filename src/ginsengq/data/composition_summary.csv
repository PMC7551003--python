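# Published mg-per-g ginsenoside composition summaries (mean, sample SD,
# number of contributing sources) for the three Panax ginseng processing
# variants, transcribed from the printed results of a published systematic
# literature survey. SD uses the n-1 denominator.
variant,compound,mean_mg_per_g,sd_mg_per_g,n_sources
black,Rg3,5.79,3.27,6
black,Rg5,3.80,0.67,3
black,Rk1,3.07,1.37,4
red,Rb1,5.46,2.54,6
red,Rc,3.21,1.89,6
red,Rg1,2.33,0.87,6
red,Rb2,2.23,0.87,6
white,Rb1,3.64,1.55,8
white,Rg1,2.79,0.87,8
white,Rc,2.57,1.96,8
white,Rb2,1.54,0.79,8
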