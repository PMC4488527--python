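scale,attribute,mean_F,mean_M,p,fm_ratio
129,All_Sum_FiberLengthMean,30670.09535,28478.19852,0.03582,1.07
129,All_Sum_Unweighted,1020.80769,972.86667,0.00026,1.049
234,All_Sum_FiberLengthMean,51558.63408,48397.55225,0.05764,1.065
234,All_Sum_Unweighted,1826.03846,1742.66667,0.00063,1.048
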