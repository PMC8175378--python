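# Tissue depth distributions per scored brain region (beyond cranium),
# as contiguous 0.5 g/cm^2 layers centred on each depth with the given
# weight. Frontal lobe is shallowest on average; hippocampus deepest.
region,depth_g_cm2,weight
head,0.25,0.0416666666666667
head,0.75,0.0416666666666667
head,1.25,0.0416666666666667
head,1.75,0.0416666666666667
head,2.25,0.0416666666666667
head,2.75,0.0416666666666667
head,3.25,0.0416666666666667
head,3.75,0.0416666666666667
head,4.25,0.0416666666666667
head,4.75,0.0416666666666667
head,5.25,0.0416666666666667
head,5.75,0.0416666666666667
head,6.25,0.0416666666666667
head,6.75,0.0416666666666667
head,7.25,0.0416666666666667
head,7.75,0.0416666666666667
head,8.25,0.0416666666666667
head,8.75,0.0416666666666667
head,9.25,0.0416666666666667
head,9.75,0.0416666666666667
head,10.25,0.0416666666666667
head,10.75,0.0416666666666667
head,11.25,0.0416666666666667
head,11.75,0.0416666666666667
frontal,1.0,0.1
frontal,1.5,0.2
frontal,2.0,0.4
frontal,2.5,0.2
frontal,3.0,0.1
parietal,2.0,0.1
parietal,2.5,0.2
parietal,3.0,0.4
parietal,3.5,0.2
parietal,4.0,0.1
temporal,2.0,0.1
temporal,2.5,0.2
temporal,3.0,0.4
temporal,3.5,0.2
temporal,4.0,0.1
occipital,2.0,0.1
occipital,2.5,0.2
occipital,3.0,0.4
occipital,3.5,0.2
occipital,4.0,0.1
hippocampus,4.0,0.1
hippocampus,4.5,0.2
hippocampus,5.0,0.4
hippocampus,5.5,0.2
hippocampus,6.0,0.1
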