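# Doses (cGy) deposited in a human head by 35 large historical SEP events
# (Aug 1997 - Dec 2006) under aluminium shields of 0/2mm/5mm/2cm/5cm/10cm,
# plus doses in five brain regions behind a 2 mm Al shield.
# Values transcribed at printed precision (including rounded zeros).
# unit=cGy
# low_confidence: the "30 Sep 1999" date breaks chronological order and may
# be "30 Sep 1998" in the original; the "10 Nov 2004" shield row is
# typographically ambiguous in the source. Statistics over this fixture use
# means across events, which are robust to single-cell ambiguity.
event,no_shield,al_2mm,al_5mm,al_2cm,al_5cm,al_10cm,frontal_2mm,parietal_2mm,temporal_2mm,occipital_2mm,hippocampus_2mm
6 Nov 1997,52,12,4,0.9,0.2,0,6,4.6,4.4,4.3,1.5
20 Apr 1998,123,39,13,2,0.4,0.1,13,9,9,8,5
24 Aug 1998,32,4,1.4,0.2,0,0,0.63,0.5,0.4,0.4,0.17
30 Sep 1999,31,5,2,0.4,0,0,1,0.8,0.7,0.7,0.3
14 Nov 1998,13,4,2,0,0,0,1.4,1.17,1.14,1.2,0.6
14 July 2000,2005,741,345,78,22,6,179,144,139,141,62
8 Nov 2000,1354,542,283,71,20,5,159,132,128,130,64
26 Nov 2000,26,4,1.5,0.3,0,0,0.69,0.53,0.5,0.5,0.19
2 Feb 2001,58,15,6,1.1,0.3,0,2.9,2.3,2.1,2.1,0.85
10 Feb 2001,10,2,0.7,0.1,0,0,0.36,0.28,0.26,0.25,0.1
12 Feb 2001,19,1,0.2,0,0,0,0.07,0.05,0.05,0.04,0
15 Feb 2001,79,39,28,14,7,3,21,19,18,17,12
18 Feb 2001,20,9,6,3,1.4,0.6,4.6,4.1,4.1,4,2.6
16 Aug 2001,28,13,8,3,1.4,0.6,5.7,4.8,4.8,4.3,2.8
24 Sep 2001,426,92,41,9,2,0.8,21,17,16,16,7
1 Oct 2001,70,8,1.7,0.1,0,0,0.6,0.4,0.35,0.3,0.07
4 Nov 2001,2255,736,256,34,7,1.7,110,82,77,76,26
22 Nov 2001,591,83,24,2,0.5,0.1,9,7,7,6,2
26 Dec 2001,48,18,10,3,1.3,0.5,6.3,5.7,5.3,5.5,2.9
21 Apr 2002,267,92,36,6,1.4,0.4,16.6,12.9,12.2,12,4.6
24 Aug 2002,29,9,4,1.3,0.5,0.2,2.8,2.5,2.3,2.3,1
26 Oct 2003,12,3,1.6,0.4,0.1,0,0.9,0.7,0.7,0.7,0.3
28 Oct 2003,1268,357,174,43,13,4,94,77,76,78,35
29 Oct 2003,244,68,36,10,3,1.2,21,18,17,18,9
2 Nov 2003,89,34,15,3,1,0.3,8,7,7,6,3
7 Nov 2004,12,1.5,0.5,0,0,0,0.27,0.21,0.2,0.2,0.07
10 Nov 2004,12,6,4,2,1.4,0.3,3.7,3.4,3.3,3.5,2.3
16 Jan 2005,27,4,2,0.4,0.1,0,1,0.78,0.74,0.7,0.3
17 Jan 2005,362,108,35,4,0.9,0.2,15,11,11,10,3
20 Jan 2005,158,90,69,37,20,10,53,49,48,50,34
13 May 2005,22,1.3,0.38,0,0,0,0.16,0.11,0.1,0.1,0.03
22 Aug 2005,19,2,0.6,0,0,0,0.24,0.18,0.16,0.15,0.05
7 Sep 2005,135,25,10,1.7,0.4,0.1,4.6,3.6,3.4,3,1.3
6 Dec 2006,174,44,21,5,1.5,0.4,11,8.9,8.6,8.4,3.9
13 Dec 2006,81,40,26,10,4,1.6,17,15,14.7,14.5,8.5
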