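mature_id	fold_regulation
hsa-miR-4732-3p	10.29
hsa-miR-142-5p	9.28
hsa-miR-877-3p	7.75
hsa-miR-3141	6.43
hsa-miR-2467-3p	5.91
hsa-miR-7-5p	5.52
hsa-miR-324-5p	5.11
hsa-miR-942-5p	4.87
hsa-miR-550a-5p	4.64
hsa-miR-10b-5p	4.33
hsa-miR-361-3p	3.87
hsa-miR-2110	3.85
hsa-miR-548o-5p	3.79
hsa-miR-331-3p	3.74
hsa-miR-769-5p	3.66
hsa-miR-18a-5p	3.66
hsa-miR-3191-3p	3.64
hsa-miR-140-5p	3.61
hsa-miR-1587	3.59
hsa-miR-130b-3p	3.49
hsa-miR-99a-5p	3.35
hsa-miR-3185	3.33
hsa-miR-596	3.3
hsa-miR-181c-5p	3.26
hsa-miR-138-1-3p	3.17
hsa-miR-4505	3.15
hsa-miR-1539	3.1
hsa-miR-29b-3p	3
hsa-miR-193a-5p	2.92
hsa-miR-376c-3p	2.82
hsa-miR-3176	2.56
hsa-miR-1183	2.4
hsa-miR-501-5p	2.38
hsa-miR-574-3p	2.32
hsa-miR-1207-5p	2.3
hsa-miR-28-3p	2.27
hsa-miR-874-3p	2.24
hsa-miR-92b-3p	2.19
hsa-miR-361-5p	2.19
hsa-miR-3622a-5p	2.18
hsa-miR-339-3p	2.16
hsa-miR-375	2.16
hsa-miR-4306	2.13
hsa-miR-154-5p	2.12
hsa-miR-199b-5p	2.1
hsa-miR-454-3p	2.08
hsa-miR-1976	2.02
hsa-miR-378b	2.01
hsa-miR-625-3p	2.01
hsa-miR-629-5p	-6.13
hsa-miR-152-3p	-5.53
hsa-miR-1307-3p	-5.3
hsa-miR-3651	-5.23
hsa-miR-345-5p	-5.08
hsa-miR-4323	-4.52
hsa-miR-30e-3p	-4.25
hsa-miR-487b-3p	-4.05
hsa-miR-18a-3p	-3.83
hsa-miR-378a-5p	-3.75
hsa-miR-502-3p	-3.72
hsa-miR-181a-5p	-3.67
hsa-miR-378e	-3.2
hsa-miR-590-5p	-3
hsa-miR-421	-2.84
hsa-miR-301a-3p	-2.84
hsa-miR-206	-2.74
hsa-let-7a-3p	-2.72
hsa-miR-598-3p	-2.72
hsa-miR-374a-5p	-2.72
hsa-miR-26b-3p	-2.67
hsa-miR-192-5p	-2.67
hsa-miR-505-3p	-2.61
hsa-miR-199a-5p	-2.6
hsa-miR-3923	-2.58
hsa-miR-3653-3p	-2.51
hsa-miR-15a-5p	-2.49
hsa-miR-1-3p	-2.42
hsa-miR-378a-3p	-2.2
hsa-miR-485-5p	-2.15
hsa-miR-338-3p	-2.12
hsa-miR-199b-3p	-2.08
hsa-miR-151b	-2.05
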