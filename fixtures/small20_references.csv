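sample_id,analyte,concentration_mg_per_ml
P1S01,glycyrrhizic_acid,0.505230353227
P1S02,glycyrrhizic_acid,1.17796647875
P1S03,glycyrrhizic_acid,1.82235814266
P1S04,glycyrrhizic_acid,1.89761613515
P1S05,glycyrrhizic_acid,2.12124165281
P1S06,glycyrrhizic_acid,2.33208507756
P1S07,glycyrrhizic_acid,2.19746085051
P1S08,glycyrrhizic_acid,2.35058053495
P2S01,glycyrrhizic_acid,0.275102986917
P2S02,glycyrrhizic_acid,0.690915819328
P2S03,glycyrrhizic_acid,0.783352421751
P2S04,glycyrrhizic_acid,1.11257343495
P2S05,glycyrrhizic_acid,1.17722630446
P2S06,glycyrrhizic_acid,0.999117543871
P3S01,glycyrrhizic_acid,0.098062954074
P3S02,glycyrrhizic_acid,0.255806883171
P3S03,glycyrrhizic_acid,0.304220756575
P3S04,glycyrrhizic_acid,0.42834417389
P3S05,glycyrrhizic_acid,0.414783035357
P3S06,glycyrrhizic_acid,0.385196696733
P1S01,liquiritin,0.222820596288
P1S02,liquiritin,0.488188091229
P1S03,liquiritin,0.69902948846
P1S04,liquiritin,0.676507471071
P1S05,liquiritin,0.688606673976
P1S06,liquiritin,0.791998313025
P1S07,liquiritin,0.758704063296
P1S08,liquiritin,0.749186664765
P2S01,liquiritin,0.122144028877
P2S02,liquiritin,0.317016258203
P2S03,liquiritin,0.348191401955
P2S04,liquiritin,0.418754770425
P2S05,liquiritin,0.387924230083
P2S06,liquiritin,0.41977039382
P3S01,liquiritin,0.0388169685692
P3S02,liquiritin,0.0836322370157
P3S03,liquiritin,0.129910372178
P3S04,liquiritin,0.14589600052
P3S05,liquiritin,0.146085545239
P3S06,liquiritin,0.134933995164
P1S01,isoliquiritin,0.0413073676211
P1S02,isoliquiritin,0.0790007203729
P1S03,isoliquiritin,0.113125466136
P1S04,isoliquiritin,0.106034461779
P1S05,isoliquiritin,0.0912411081093
P1S06,isoliquiritin,0.0928772813104
P1S07,isoliquiritin,0.108015195268
P1S08,isoliquiritin,0.103396790374
P2S01,isoliquiritin,0.0213509524184
P2S02,isoliquiritin,0.0416636353355
P2S03,isoliquiritin,0.0571917444431
P2S04,isoliquiritin,0.0570615027183
P2S05,isoliquiritin,0.0519288002024
P2S06,isoliquiritin,0.0616023144919
P3S01,isoliquiritin,0.00461540938007
P3S02,isoliquiritin,0.0094650036046
P3S03,isoliquiritin,0.0123046272144
P3S04,isoliquiritin,0.0153719533904
P3S05,isoliquiritin,0.0123488214644
P3S06,isoliquiritin,0.0155501849628
P1S01,total_flavonoids,0.764538488961
P1S02,total_flavonoids,1.58202774514
P1S03,total_flavonoids,1.77579075271
P1S04,total_flavonoids,2.10658158251
P1S05,total_flavonoids,2.01166084748
P1S06,total_flavonoids,1.92992077866
P1S07,total_flavonoids,1.93048914313
P1S08,total_flavonoids,2.05969221671
P2S01,total_flavonoids,0.370292437968
P2S02,total_flavonoids,0.855386140067
P2S03,total_flavonoids,0.995533506147
P2S04,total_flavonoids,0.932970831908
P2S05,total_flavonoids,0.881814357427
P2S06,total_flavonoids,1.07103110831
P3S01,total_flavonoids,0.123125330834
P3S02,total_flavonoids,0.262124760528
P3S03,total_flavonoids,0.353919763129
P3S04,total_flavonoids,0.37789862794
P3S05,total_flavonoids,0.342281476991
P3S06,total_flavonoids,0.366019350599
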