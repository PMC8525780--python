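trait,split,n_obs,n_val,transformation,n_comp,rmse,range,pct_rmse,r2
Vcmax25,random,302,59,sqrt,18,13.1,149.3,8.8,0.74
Vcmax25,species,302,34,sqrt,18,11.2,149.3,7.5,0.86
Vcmax25,site,302,43,sqrt,18,8.2,149.3,5.5,0.66
Jmax25,random,286,56,sqrt,18,19.8,237.3,8.4,0.73
Jmax25,species,286,34,sqrt,18,17.6,237.3,7.4,0.86
Jmax25,site,286,30,sqrt,18,16.6,237.3,7.0,0.38
Tp25,random,99,18,none,3,1.52,12.3,12.4,0.64
Tp25,species,99,19,none,3,1.44,12.3,11.7,0.74
Rdark25,random,168,49,none,11,0.27,2.8,9.5,0.58
Rdark25,species,168,12,none,11,0.23,2.8,8.4,0.50
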