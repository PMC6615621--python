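sex_code,group,outcome,age,spline_value
1,Caucasian,FVC,4,-0.9
1,Caucasian,FVC,10,-0.35
1,Caucasian,FVC,18,0.0
1,Caucasian,FVC,25,0.03
1,Caucasian,FVC,40,-0.03
1,Caucasian,FVC,60,-0.15
1,Caucasian,FVC,80,-0.3
1,Caucasian,FEV1,4,-0.9
1,Caucasian,FEV1,10,-0.35
1,Caucasian,FEV1,18,0.0
1,Caucasian,FEV1,25,0.03
1,Caucasian,FEV1,40,-0.03
1,Caucasian,FEV1,60,-0.15
1,Caucasian,FEV1,80,-0.3
1,AfricanAmerican,FVC,4,-0.9
1,AfricanAmerican,FVC,10,-0.35
1,AfricanAmerican,FVC,18,0.0
1,AfricanAmerican,FVC,25,0.03
1,AfricanAmerican,FVC,40,-0.03
1,AfricanAmerican,FVC,60,-0.15
1,AfricanAmerican,FVC,80,-0.3
1,AfricanAmerican,FEV1,4,-0.9
1,AfricanAmerican,FEV1,10,-0.35
1,AfricanAmerican,FEV1,18,0.0
1,AfricanAmerican,FEV1,25,0.03
1,AfricanAmerican,FEV1,40,-0.03
1,AfricanAmerican,FEV1,60,-0.15
1,AfricanAmerican,FEV1,80,-0.3
1,NorthEastAsian,FVC,4,-0.9
1,NorthEastAsian,FVC,10,-0.35
1,NorthEastAsian,FVC,18,0.0
1,NorthEastAsian,FVC,25,0.03
1,NorthEastAsian,FVC,40,-0.03
1,NorthEastAsian,FVC,60,-0.15
1,NorthEastAsian,FVC,80,-0.3
1,NorthEastAsian,FEV1,4,-0.9
1,NorthEastAsian,FEV1,10,-0.35
1,NorthEastAsian,FEV1,18,0.0
1,NorthEastAsian,FEV1,25,0.03
1,NorthEastAsian,FEV1,40,-0.03
1,NorthEastAsian,FEV1,60,-0.15
1,NorthEastAsian,FEV1,80,-0.3
1,SouthEastAsian,FVC,4,-0.9
1,SouthEastAsian,FVC,10,-0.35
1,SouthEastAsian,FVC,18,0.0
1,SouthEastAsian,FVC,25,0.03
1,SouthEastAsian,FVC,40,-0.03
1,SouthEastAsian,FVC,60,-0.15
1,SouthEastAsian,FVC,80,-0.3
1,SouthEastAsian,FEV1,4,-0.9
1,SouthEastAsian,FEV1,10,-0.35
1,SouthEastAsian,FEV1,18,0.0
1,SouthEastAsian,FEV1,25,0.03
1,SouthEastAsian,FEV1,40,-0.03
1,SouthEastAsian,FEV1,60,-0.15
1,SouthEastAsian,FEV1,80,-0.3
1,Other,FVC,4,-0.9
1,Other,FVC,10,-0.35
1,Other,FVC,18,0.0
1,Other,FVC,25,0.03
1,Other,FVC,40,-0.03
1,Other,FVC,60,-0.15
1,Other,FVC,80,-0.3
1,Other,FEV1,4,-0.9
1,Other,FEV1,10,-0.35
1,Other,FEV1,18,0.0
1,Other,FEV1,25,0.03
1,Other,FEV1,40,-0.03
1,Other,FEV1,60,-0.15
1,Other,FEV1,80,-0.3
2,Caucasian,FVC,4,-0.9
2,Caucasian,FVC,10,-0.35
2,Caucasian,FVC,18,0.0
2,Caucasian,FVC,25,0.03
2,Caucasian,FVC,40,-0.03
2,Caucasian,FVC,60,-0.15
2,Caucasian,FVC,80,-0.3
2,Caucasian,FEV1,4,-0.9
2,Caucasian,FEV1,10,-0.35
2,Caucasian,FEV1,18,0.0
2,Caucasian,FEV1,25,0.03
2,Caucasian,FEV1,40,-0.03
2,Caucasian,FEV1,60,-0.15
2,Caucasian,FEV1,80,-0.3
2,AfricanAmerican,FVC,4,-0.9
2,AfricanAmerican,FVC,10,-0.35
2,AfricanAmerican,FVC,18,0.0
2,AfricanAmerican,FVC,25,0.03
2,AfricanAmerican,FVC,40,-0.03
2,AfricanAmerican,FVC,60,-0.15
2,AfricanAmerican,FVC,80,-0.3
2,AfricanAmerican,FEV1,4,-0.9
2,AfricanAmerican,FEV1,10,-0.35
2,AfricanAmerican,FEV1,18,0.0
2,AfricanAmerican,FEV1,25,0.03
2,AfricanAmerican,FEV1,40,-0.03
2,AfricanAmerican,FEV1,60,-0.15
2,AfricanAmerican,FEV1,80,-0.3
2,NorthEastAsian,FVC,4,-0.9
2,NorthEastAsian,FVC,10,-0.35
2,NorthEastAsian,FVC,18,0.0
2,NorthEastAsian,FVC,25,0.03
2,NorthEastAsian,FVC,40,-0.03
2,NorthEastAsian,FVC,60,-0.15
2,NorthEastAsian,FVC,80,-0.3
2,NorthEastAsian,FEV1,4,-0.9
2,NorthEastAsian,FEV1,10,-0.35
2,NorthEastAsian,FEV1,18,0.0
2,NorthEastAsian,FEV1,25,0.03
2,NorthEastAsian,FEV1,40,-0.03
2,NorthEastAsian,FEV1,60,-0.15
2,NorthEastAsian,FEV1,80,-0.3
2,SouthEastAsian,FVC,4,-0.9
2,SouthEastAsian,FVC,10,-0.35
2,SouthEastAsian,FVC,18,0.0
2,SouthEastAsian,FVC,25,0.03
2,SouthEastAsian,FVC,40,-0.03
2,SouthEastAsian,FVC,60,-0.15
2,SouthEastAsian,FVC,80,-0.3
2,SouthEastAsian,FEV1,4,-0.9
2,SouthEastAsian,FEV1,10,-0.35
2,SouthEastAsian,FEV1,18,0.0
2,SouthEastAsian,FEV1,25,0.03
2,SouthEastAsian,FEV1,40,-0.03
2,SouthEastAsian,FEV1,60,-0.15
2,SouthEastAsian,FEV1,80,-0.3
2,Other,FVC,4,-0.9
2,Other,FVC,10,-0.35
2,Other,FVC,18,0.0
2,Other,FVC,25,0.03
2,Other,FVC,40,-0.03
2,Other,FVC,60,-0.15
2,Other,FVC,80,-0.3
2,Other,FEV1,4,-0.9
2,Other,FEV1,10,-0.35
2,Other,FEV1,18,0.0
2,Other,FEV1,25,0.03
2,Other,FEV1,40,-0.03
2,Other,FEV1,60,-0.15
2,Other,FEV1,80,-0.3
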