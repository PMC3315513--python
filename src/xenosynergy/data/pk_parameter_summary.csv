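drug,dose,auc_unit,auc_single,auc_combination,cmax_unit,cmax_single,cmax_combination,tmax_single_h,tmax_combination_h
VCR,0.15 mg/kg,mg/L*min,1.60,1.75,ng/mL,6.2,8.7,1,0.5
DEX,5 mg/kg,ng*h/mL,3279.05,6792.95,ng/mL,1760.73,2849.02,0.16,0.25
ASP,1000 U/kg,U*h/mL,87.02,99.44,U/mL,8.27,8.90,2.21,1.97
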