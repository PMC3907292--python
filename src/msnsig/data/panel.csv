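variable,target,target_hi,mode,units,protocol,marker
basal-cAMP,0.06,,absolute,uM,basal,cAMP
basal-STEPact,0.8,,absolute,fraction,basal,STEPact
basal-D32p34,0.2,0.5,absolute,uM,basal,D32p34
basal-D32p75,13.0,,absolute,uM,basal,D32p75
DAslice-D32p34,12.0,,fold-over-basal,x,DAslice,D32p34
DAslice-D32p75,0.5,,fold-over-basal,x,DAslice,D32p75
NMDAslice-D32p34,0.5,,fold-over-basal,x,NMDAslice,D32p34
NMDAslice-D32p75,0.5,,fold-over-basal,x,NMDAslice,D32p75
activateRAS-h,4.1,,fitted-parameter,,activateRAS,RASRAF_fraction
activateRAS-K,0.8,,fitted-parameter,uM,activateRAS,RASRAF_fraction
trafficNMDAR-k,0.15,,fitted-parameter,1/min,trafficNMDAR,NMDAR_current_scale
haploD1R-ERKpp,0.5,,ratio-to-WT,x,APA,ERKpp
haploD1R-GluR1p,1.0,,ratio-to-WT,x,APA,GluR1p845
haploGolf-ERKpp,0.9,,ratio-to-WT,x,APA,ERKpp
haploGolf-GluR1p,0.6,,ratio-to-WT,x,APA,GluR1p845
D32KO-ERKpp,0.4,,ratio-to-WT,x,APA,ERKpp
D32KO-GluR1p,0.35,,ratio-to-WT,x,APA,GluR1p845
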