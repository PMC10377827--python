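mature_id	fold_regulation
hsa-miR-4301	142.74
hsa-let-7b-5p	90.34
hsa-miR-1287-5p	50.12
hsa-let-7a-5p	48.41
hsa-miR-1913	42.73
hsa-miR-523-5p	34.47
hsa-miR-26b-5p	31.06
hsa-miR-195-5p	25.76
hsa-miR-1587	21.07
hsa-miR-3135b	18.99
hsa-miR-1260a	17.23
hsa-miR-1260b	16.53
hsa-miR-20b-5p	15.97
hsa-miR-1281	14.9
hsa-miR-3131	14.49
hsa-miR-4687-5p	13.24
hsa-miR-3200-5p	13.06
hsa-miR-100-5p	12.88
hsa-let-7c-5p	11.94
hsa-miR-365b-3p	11.77
hsa-let-7f-5p	11.37
hsa-miR-671-3p	11.29
hsa-miR-625-3p	11.29
hsa-miR-4651	10.76
hsa-miR-4505	9.9
hsa-miR-144-3p	9.76
hsa-miR-1237-3p	9.56
hsa-miR-378g	9.36
hsa-miR-1183	9.11
hsa-miR-596	8.92
hsa-miR-1910-5p	8.86
hsa-miR-3141	8.44
hsa-miR-185-5p	8.15
hsa-miR-3610	7.93
hsa-miR-877-3p	7.71
hsa-miR-1207-5p	7.61
hsa-miR-3911	7.55
hsa-miR-99a-5p	7.55
hsa-miR-3183	7.4
hsa-let-7e-5p	7.35
hsa-miR-223-3p	7.2
hsa-miR-373-5p	6.31
hsa-miR-4274	6.18
hsa-miR-370-3p	6.05
hsa-miR-101-3p	5.93
hsa-miR-181c-5p	5.69
hsa-miR-4689	5.65
hsa-miR-142-5p	5.57
hsa-miR-1301-3p	5.53
hsa-miR-106b-5p	5.23
hsa-miR-3907	4.92
hsa-miR-1290	4.81
hsa-miR-877-5p	4.71
hsa-miR-1909-5p	4.68
hsa-miR-4732-5p	4.68
hsa-miR-320e	4.52
hsa-miR-138-1-3p	4.49
hsa-let-7d-5p	4.46
hsa-miR-10a-5p	4.25
hsa-miR-1203	4.25
hsa-miR-3646	4.19
hsa-miR-34c-3p	4.05
hsa-miR-181c-3p	4.02
hsa-miR-1539	3.96
hsa-miR-3185	3.96
hsa-miR-4688	3.96
hsa-miR-3191-3p	3.91
hsa-miR-4291	3.88
hsa-miR-363-3p	3.88
hsa-miR-219a-1-3p	3.83
hsa-miR-628-3p	3.8
hsa-miR-1225-3p	3.62
hsa-miR-2467-3p	3.55
hsa-miR-375	3.5
hsa-let-7i-5p	3.43
hsa-miR-324-3p	3.36
hsa-miR-27b-3p	3.36
hsa-miR-4516	3.33
hsa-miR-92b-3p	3.2
hsa-miR-675-3p	3.2
hsa-miR-490-3p	3.15
hsa-miR-146b-5p	3.09
hsa-miR-4267	2.98
hsa-miR-425-3p	2.96
hsa-miR-942-5p	2.92
hsa-miR-374c-5p	2.86
hsa-miR-3176	2.8
hsa-miR-550a-5p	2.78
hsa-miR-2276-3p	2.75
hsa-miR-425-5p	2.75
hsa-miR-190a-5p	2.67
hsa-miR-10b-5p	2.6
hsa-miR-139-3p	2.58
hsa-miR-188-5p	2.46
hsa-miR-451a	2.41
hsa-miR-1247-5p	2.39
hsa-miR-664a-3p	2.37
hsa-miR-361-3p	2.32
hsa-miR-2110	2.31
hsa-miR-605-5p	2.29
hsa-miR-4302	2.29
hsa-miR-1180-3p	2.28
hsa-miR-548o-5p	2.28
hsa-miR-193b-3p	2.28
hsa-miR-331-3p	2.25
hsa-miR-7-1-3p	2.25
hsa-miR-769-5p	2.2
hsa-miR-4538	2.18
hsa-miR-140-5p	2.17
hsa-miR-19a-3p	2.17
hsa-miR-378b	2.04
hsa-miR-4454	2.04
hsa-miR-328-3p	-30.54
hsa-miR-598-3p	-13.96
hsa-miR-152-3p	-12.84
hsa-miR-502-3p	-11.74
hsa-miR-382-5p	-11.49
hsa-miR-409-3p	-11.49
hsa-miR-181d-5p	-8.07
hsa-miR-28-5p	-7.91
hsa-miR-1307-3p	-7.58
hsa-miR-154-5p	-7.03
hsa-miR-424-3p	-6.98
hsa-miR-132-3p	-6.79
hsa-miR-181a-5p	-6.65
hsa-miR-30a-3p	-6.56
hsa-miR-4323	-6.25
hsa-miR-3651	-6.03
hsa-miR-210-3p	-5.91
hsa-miR-627-5p	-5.87
hsa-miR-339-5p	-5.47
hsa-miR-34a-5p	-5.4
hsa-miR-199a-5p	-4.87
hsa-miR-4258	-4.57
hsa-miR-378a-3p	-4.45
hsa-miR-340-5p	-4.12
hsa-miR-93-3p	-3.87
hsa-miR-130a-3p	-3.69
hsa-miR-15a-5p	-3.35
hsa-miR-151a-5p	-3.3
hsa-miR-421	-3.26
hsa-miR-199b-3p	-3.19
hsa-miR-1976	-3.1
hsa-miR-194-5p	-3.06
hsa-miR-324-5p	-2.95
hsa-miR-93-5p	-2.93
hsa-miR-125a-5p	-2.81
hsa-miR-191-5p	-2.78
hsa-miR-224-5p	-2.76
hsa-miR-151a-3p	-2.76
hsa-miR-24-3p	-2.76
hsa-miR-192-5p	-2.74
hsa-miR-19b-3p	-2.68
hsa-miR-16-5p	-2.66
hsa-miR-146a-5p	-2.64
hsa-miR-186-5p	-2.61
hsa-miR-433-3p	-2.59
hsa-miR-126-3p	-2.55
hsa-miR-505-3p	-2.52
hsa-miR-21-5p	-2.37
hsa-miR-151b	-2.35
hsa-miR-25-3p	-2.16
hsa-miR-342-3p	-2.02
hsa-miR-15b-5p	-2.02
hsa-miR-7-5p	-2
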