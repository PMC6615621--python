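sex_code,group,outcome,a0,a1,a2
1,Caucasian,FVC,-11.936,2.6,0.03
1,Caucasian,FEV1,-12.1592,2.6,0.03
1,AfricanAmerican,FVC,-12.0638,2.6,0.03
1,AfricanAmerican,FEV1,-12.287,2.6,0.03
1,NorthEastAsian,FVC,-11.9873,2.6,0.03
1,NorthEastAsian,FEV1,-12.2105,2.6,0.03
1,SouthEastAsian,FVC,-12.0194,2.6,0.03
1,SouthEastAsian,FEV1,-12.2425,2.6,0.03
1,Other,FVC,-11.9979,2.6,0.03
1,Other,FEV1,-12.221,2.6,0.03
2,Caucasian,FVC,-12.0985,2.6,0.03
2,Caucasian,FEV1,-12.3217,2.6,0.03
2,AfricanAmerican,FVC,-12.2264,2.6,0.03
2,AfricanAmerican,FEV1,-12.4495,2.6,0.03
2,NorthEastAsian,FVC,-12.1498,2.6,0.03
2,NorthEastAsian,FEV1,-12.373,2.6,0.03
2,SouthEastAsian,FVC,-12.1819,2.6,0.03
2,SouthEastAsian,FEV1,-12.4051,2.6,0.03
2,Other,FVC,-12.1604,2.6,0.03
2,Other,FEV1,-12.3836,2.6,0.03
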