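mirna_id	mirna_status	circ_id	circ_status	total_energy	position
hsa-let-7a-5p	Up	chr17_67945408_67975958	Up	−22.32	1049
hsa-let-7a-5p	Up	chr2_159729008_159752571	Down	−26.91	297
hsa-let-7b-5p	Up	chr17_67945408_67975958	Up	−20.39	1047
hsa-let-7b-5p	Up	chr1_150230570_150231926	Down	−20.57	204
hsa-let-7b-5p	Up	chr2_159729008_159752571	Down	−24.8	297
hsa-miR-16-5p	Up	chr17_67945408_67975958	Up	−21.93	972
hsa-miR-16-5p	Up	chr15_76274411_76295737	Down	−21.26	93
hsa-miR-16-5p	Up	chr15_98707561_98708107	Down	−20.88	146
hsa-miR-16-5p	Up	chr21_44855209_44861271	Down	−20.24	168
hsa-miR-16-5p	Up	chr8_37877108_37877551	Down	−20.92	354
hsa-miR-18a-5p	Up	chr8_99502835_99511512	Down	−21.56	243
hsa-miR-18a-5p	Up	chr3_15411244_15415942	Down	−23.66	129
hsa-miR-18a-5p	Up	chr6_147260614_147278204	Down	−24.63	24
hsa-miR-92a-3p	Down	chr14_31127784_31133675	Down	−23.03	836
hsa-miR-92a-3p	Down	chr4_55411613_55417985	Down	−20.76	176
hsa-let-7g-5p	Up	chr14_31127784_31133675	Down	−20.68	8
hsa-let-7g-5p	Up	chr2_159729008_159752571	Down	−31.76	297
hsa-let-7i-5p	Up	chr14_31127784_31133675	Down	−22.24	86
hsa-let-7i-5p	Up	chr2_159729008_159752571	Down	−26.91	297
hsa-miR-30b-5p	Down	chr5_109713519_109729513	Down	−21.36	251
hsa-miR-654-3p	Down	chr10_26500818_26503274	Down	−21.12	45
hsa-miR-654-3p	Down	chr5_55645788_55664863	Down	−20.32	28
hsa-miR-1271-5p	Down	chr5_154029488_154034967	Down	−21.49	104
hsa-miR-1271-5p	Down	chr3_15411244_15415942	Down	−20.01	397
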