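study,xenograft,treatment,median_efs,n_mice,lgd,outcome,flag
abt737,ALL-2,Control,19.7,6,,dod,
abt737,ALL-2,ABT-737,27.3,8,7.6,dod,
abt737,ALL-2,VXL,78.6,8,58.9,dod,
abt737,ALL-2,VXL/ABT-737,99.7,7,80.0,dod,
abt737,ALL-3,Control,15.8,8,,alive,
abt737,ALL-3,VXL,>133.4,8,>117.6,alive,
abt737,ALL-4,Control,10.1,8,,dod,
abt737,ALL-4,ABT-737,8.5,8,0,dod,
abt737,ALL-4,VXL,32.9,8,22.8,dod,
abt737,ALL-4,VXL/ABT-737,39.3,8,29.2,dod,
abt737,ALL-7,Control,12.7,8,,dod,
abt737,ALL-7,VXL,58.9,8,46.2,dod,
abt737,ALL-8,Control,10.9,8,,dod,
abt737,ALL-8,ABT-737,10.7,8,0,dod,
abt737,ALL-8,VXL,64.6,8,53.7,dod,
abt737,ALL-8,VXL/ABT-737,76.5,7,76.5,dod,lgd-discrepant
abt737,ALL-10,Control,12.5,7,,alive,
abt737,ALL-10,ABT-737,26.0,8,13.5,alive,
abt737,ALL-10,VXL,71.8,8,59.3,alive,
abt737,ALL-10,VXL/ABT-737,78.3,8,65.8,alive,
abt737,ALL-11,Control,19.3,8,,alive,
abt737,ALL-11,VXL,119,10,99.7,alive,
abt737,ALL-16,Control,13.2,8,,alive,
abt737,ALL-16,VXL,>160.0,5,>146.8,alive,
abt737,ALL-17,Control,15.1,6,,alive,
abt737,ALL-17,ABT-737,28.9,8,13.8,alive,
abt737,ALL-17,VXL,72,7,56.9,alive,
abt737,ALL-17,VXL/ABT-737,72,7,56.9,alive,
abt737,ALL-19,Control,6.9,8,,dod,
abt737,ALL-19,VXL,40.8,7,33.9,dod,
ato,ALL-4,Control,5.1,8,,dod,
ato,ALL-4,ATO,10.5,8,5.4,dod,
ato,ALL-4,VXL,40.3,7,35.2,dod,
ato,ALL-4,VXL/ATO,42.3,7,37.2,dod,
ato,ALL-7,Control,11.5,7,,dod,
ato,ALL-7,ATO,10.8,7,0,dod,
ato,ALL-7,VXL,63.3,6,51.8,dod,
ato,ALL-7,VXL/ATO,70.8,7,59.3,dod,
ato,ALL-8,Control,10.3,7,,dod,
ato,ALL-8,ATO,12.4,7,2.1,dod,
ato,ALL-8,VXL,65.6,7,55.3,dod,
ato,ALL-8,VXL/ATO,68.4,6,58.1,dod,
ato,ALL-19,Control,9.3,7,,dod,
ato,ALL-19,ATO,11.9,9,2.6,dod,
ato,ALL-19,VXL,55.2,8,45.9,dod,
ato,ALL-19,VXL/ATO,52.9,9,43.6,dod,
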