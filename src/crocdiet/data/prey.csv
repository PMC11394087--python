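stomach_id,category,rank,group,count,volume_ml
S01,Coleoptera,order,invertebrate,1,0.3888888888888889
S02,Coleoptera,order,invertebrate,1,0.3888888888888889
S03,Coleoptera,order,invertebrate,1,0.3888888888888889
S04,Coleoptera,order,invertebrate,1,0.3888888888888889
S05,Coleoptera,order,invertebrate,1,0.3888888888888889
S06,Coleoptera,order,invertebrate,1,0.3888888888888889
S07,Coleoptera,order,invertebrate,1,0.3888888888888889
S08,Coleoptera,order,invertebrate,1,0.3888888888888889
S09,Coleoptera,order,invertebrate,1,0.3888888888888889
S01,Hemiptera,order,invertebrate,1,0.21000000000000002
S02,Hemiptera,order,invertebrate,1,0.21000000000000002
S03,Hemiptera,order,invertebrate,1,0.21000000000000002
S04,Hemiptera,order,invertebrate,1,0.21000000000000002
S05,Hemiptera,order,invertebrate,1,0.21000000000000002
S06,Hemiptera,order,invertebrate,1,0.21000000000000002
S07,Hemiptera,order,invertebrate,1,0.21000000000000002
S08,Hemiptera,order,invertebrate,1,0.21000000000000002
S09,Hemiptera,order,invertebrate,1,0.21000000000000002
S10,Hemiptera,order,invertebrate,1,0.21000000000000002
S01,Araneae,order,invertebrate,1,0.1625
S02,Araneae,order,invertebrate,1,0.1625
S03,Araneae,order,invertebrate,1,0.1625
S04,Araneae,order,invertebrate,1,0.1625
S05,Araneae,order,invertebrate,1,0.1625
S06,Araneae,order,invertebrate,1,0.1625
S07,Araneae,order,invertebrate,1,0.1625
S08,Araneae,order,invertebrate,1,0.1625
S01,Blattodea,order,invertebrate,1,0.5
S01,Hymenoptera,order,invertebrate,1,0.1
S02,Hymenoptera,order,invertebrate,1,0.1
S01,Diptera,order,invertebrate,1,0.9
S01,Odonata,order,invertebrate,1,0.3
S01,Scorpiones,order,invertebrate,1,0.1
S02,Scorpiones,order,invertebrate,1,0.1
S11,Coleoptera,order,invertebrate,1,0.9
S12,Coleoptera,order,invertebrate,1,0.9
S13,Coleoptera,order,invertebrate,1,0.9
S14,Coleoptera,order,invertebrate,1,0.9
S15,Coleoptera,order,invertebrate,1,0.9
S16,Coleoptera,order,invertebrate,1,0.9
S11,Hemiptera,order,invertebrate,1,0.575
S12,Hemiptera,order,invertebrate,1,0.575
S13,Hemiptera,order,invertebrate,1,0.575
S14,Hemiptera,order,invertebrate,1,0.575
S11,Araneae,order,invertebrate,1,0.35000000000000003
S12,Araneae,order,invertebrate,1,0.35000000000000003
S13,Araneae,order,invertebrate,1,0.35000000000000003
S14,Araneae,order,invertebrate,1,0.35000000000000003
S15,Araneae,order,invertebrate,1,0.35000000000000003
S16,Araneae,order,invertebrate,1,0.35000000000000003
S11,Blattodea,order,invertebrate,1,1.3
S11,Hymenoptera,order,invertebrate,1,0.43333333333333335
S12,Hymenoptera,order,invertebrate,1,0.43333333333333335
S13,Hymenoptera,order,invertebrate,1,0.43333333333333335
S11,Fish,class,vertebrate,1,0.3
S11,Diptera,order,invertebrate,1,0.1
S11,Odonata,order,invertebrate,1,0.5
S11,Scorpiones,order,invertebrate,1,0.2
S18,Coleoptera,order,invertebrate,1,0.4083333333333334
S19,Coleoptera,order,invertebrate,1,0.4083333333333334
S20,Coleoptera,order,invertebrate,1,0.4083333333333334
S21,Coleoptera,order,invertebrate,1,0.4083333333333334
S22,Coleoptera,order,invertebrate,1,0.4083333333333334
S23,Coleoptera,order,invertebrate,1,0.4083333333333334
S24,Coleoptera,order,invertebrate,1,0.4083333333333334
S25,Coleoptera,order,invertebrate,1,0.4083333333333334
S26,Coleoptera,order,invertebrate,1,0.4083333333333334
S27,Coleoptera,order,invertebrate,1,0.4083333333333334
S28,Coleoptera,order,invertebrate,1,0.4083333333333334
S29,Coleoptera,order,invertebrate,1,0.4083333333333334
S18,Hemiptera,order,invertebrate,1,0.3111111111111111
S19,Hemiptera,order,invertebrate,1,0.3111111111111111
S20,Hemiptera,order,invertebrate,1,0.3111111111111111
S21,Hemiptera,order,invertebrate,1,0.3111111111111111
S22,Hemiptera,order,invertebrate,1,0.3111111111111111
S23,Hemiptera,order,invertebrate,1,0.3111111111111111
S24,Hemiptera,order,invertebrate,1,0.3111111111111111
S25,Hemiptera,order,invertebrate,1,0.3111111111111111
S26,Hemiptera,order,invertebrate,1,0.3111111111111111
S18,Araneae,order,invertebrate,1,0.41111111111111115
S19,Araneae,order,invertebrate,1,0.41111111111111115
S20,Araneae,order,invertebrate,1,0.41111111111111115
S21,Araneae,order,invertebrate,1,0.41111111111111115
S22,Araneae,order,invertebrate,1,0.41111111111111115
S23,Araneae,order,invertebrate,1,0.41111111111111115
S24,Araneae,order,invertebrate,1,0.41111111111111115
S25,Araneae,order,invertebrate,1,0.41111111111111115
S26,Araneae,order,invertebrate,1,0.41111111111111115
S18,Blattodea,order,invertebrate,1,0.525
S19,Blattodea,order,invertebrate,1,0.525
S20,Blattodea,order,invertebrate,1,0.525
S21,Blattodea,order,invertebrate,1,0.525
S18,Hymenoptera,order,invertebrate,1,0.2333333333333333
S19,Hymenoptera,order,invertebrate,1,0.2333333333333333
S20,Hymenoptera,order,invertebrate,1,0.2333333333333333
S21,Hymenoptera,order,invertebrate,1,0.2333333333333333
S22,Hymenoptera,order,invertebrate,1,0.2333333333333333
S23,Hymenoptera,order,invertebrate,1,0.2333333333333333
S18,Fish,class,vertebrate,1,0.5
S19,Fish,class,vertebrate,1,0.5
S20,Fish,class,vertebrate,1,0.5
S21,Fish,class,vertebrate,1,0.5
S18,Birds,class,vertebrate,1,1.3
S18,Diptera,order,invertebrate,1,0.15
S19,Diptera,order,invertebrate,1,0.15
S18,Odonata,order,invertebrate,1,0.1
S18,Scorpiones,order,invertebrate,1,0.15
S19,Scorpiones,order,invertebrate,1,0.15
S18,Gastropods,class,invertebrate,1,0.05
S19,Gastropods,class,invertebrate,1,0.05
S20,Gastropods,class,invertebrate,1,0.05
S21,Gastropods,class,invertebrate,1,0.05
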