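mature_id	fold_regulation
hsa-miR-4301	124.8
hsa-let-7b-5p	100.66
hsa-miR-26b-5p	38.41
hsa-let-7a-5p	37.1
hsa-miR-523-5p	32.75
hsa-miR-1287-5p	26.97
hsa-miR-1913	24.14
hsa-miR-195-5p	23.16
hsa-miR-100-5p	22.37
hsa-miR-1260a	18.94
hsa-miR-365b-3p	17.43
hsa-miR-4687-5p	16.95
hsa-miR-3135b	15.49
hsa-let-7f-5p	14.66
hsa-miR-3131	13.12
hsa-miR-3183	12.67
hsa-miR-20b-5p	10.8
hsa-miR-1260b	10.44
hsa-miR-223-3p	9.4
hsa-miR-370-3p	8.9
hsa-miR-3200-5p	8.3
hsa-miR-3911	8.02
hsa-miR-4651	7.91
hsa-miR-1281	7.85
hsa-miR-378g	7.85
hsa-miR-30e-3p	7.8
hsa-miR-185-5p	7.75
hsa-miR-1237-3p	7.59
hsa-let-7c-5p	7.23
hsa-miR-144-3p	7.08
hsa-miR-671-3p	7.08
hsa-miR-101-3p	7.03
hsa-miR-1301-3p	6.88
hsa-miR-1910-5p	6.7
hsa-miR-1290	6.38
hsa-miR-3646	6.2
hsa-miR-3610	6.16
hsa-miR-4291	5.95
hsa-miR-3907	5.95
hsa-miR-1203	5.95
hsa-miR-1587	5.87
hsa-miR-4732-5p	5.79
hsa-miR-625-3p	5.63
hsa-miR-106b-5p	5.36
hsa-miR-181c-3p	5.25
hsa-miR-18a-3p	5.08
hsa-miR-4274	5.01
hsa-miR-219a-1-3p	4.8
hsa-let-7e-5p	4.74
hsa-miR-34c-3p	4.54
hsa-miR-877-5p	4.51
hsa-miR-1909-5p	4.48
hsa-miR-146b-5p	4.45
hsa-miR-4688	4.39
hsa-miR-363-3p	4.39
hsa-miR-490-3p	4.33
hsa-miR-373-5p	4.18
hsa-miR-4689	3.93
hsa-miR-4267	3.85
hsa-miR-1183	3.79
hsa-miR-629-5p	3.77
hsa-miR-10a-5p	3.69
hsa-miR-628-3p	3.66
hsa-miR-345-5p	3.64
hsa-let-7i-5p	3.61
hsa-miR-320e	3.4
hsa-let-7d-5p	3.37
hsa-miR-1207-5p	3.3
hsa-miR-27b-3p	3.17
hsa-miR-4505	3.15
hsa-miR-4516	3.12
hsa-miR-330-3p	3.06
hsa-miR-487b-3p	2.94
hsa-miR-425-5p	2.91
hsa-miR-2276-3p	2.89
hsa-miR-675-3p	2.87
hsa-miR-605-5p	2.78
hsa-miR-596	2.7
hsa-miR-19a-3p	2.7
hsa-miR-451a	2.65
hsa-miR-7-1-3p	2.54
hsa-miR-127-3p	2.5
hsa-miR-324-3p	2.43
hsa-miR-193b-3p	2.33
hsa-miR-378a-5p	2.3
hsa-miR-99a-5p	2.26
hsa-miR-374c-5p	2.19
hsa-miR-425-3p	2.16
hsa-miR-489-3p	2.15
hsa-miR-1247-5p	2.12
hsa-miR-188-5p	2.1
hsa-miR-4422	2.06
hsa-miR-664a-3p	2.06
hsa-miR-7-2-3p	2
hsa-miR-4538	2
hsa-miR-328-3p	-52.22
hsa-miR-324-5p	-15.1
hsa-miR-154-5p	-14.89
hsa-miR-382-5p	-14.59
hsa-miR-7-5p	-11.05
hsa-miR-409-3p	-9.49
hsa-miR-210-3p	-8.44
hsa-miR-181d-5p	-8.26
hsa-miR-28-5p	-8.09
hsa-miR-4258	-7.71
hsa-miR-340-5p	-6.85
hsa-miR-627-5p	-6.8
hsa-miR-4732-3p	-6.35
hsa-miR-1976	-6.26
hsa-miR-151a-5p	-5.92
hsa-miR-34a-5p	-5.53
hsa-miR-29b-3p	-5.53
hsa-miR-132-3p	-5.53
hsa-miR-224-5p	-5.49
hsa-miR-598-3p	-5.12
hsa-miR-339-5p	-4.98
hsa-miR-130b-3p	-4.68
hsa-miR-130a-3p	-4.58
hsa-miR-18a-5p	-4.31
hsa-miR-424-3p	-3.99
hsa-miR-361-5p	-3.94
hsa-miR-30a-3p	-3.88
hsa-miR-199b-5p	-3.75
hsa-miR-16-5p	-3.22
hsa-miR-342-3p	-3.17
hsa-miR-93-5p	-3.17
hsa-miR-150-5p	-3.15
hsa-miR-502-3p	-3.15
hsa-miR-194-5p	-2.98
hsa-miR-5095	-2.98
hsa-miR-193a-5p	-2.9
hsa-miR-125a-5p	-2.84
hsa-miR-433-3p	-2.65
hsa-miR-24-3p	-2.6
hsa-miR-19b-3p	-2.6
hsa-miR-186-5p	-2.58
hsa-miR-130b-5p	-2.56
hsa-miR-151a-3p	-2.54
hsa-miR-152-3p	-2.32
hsa-miR-484	-2.31
hsa-miR-320a	-2.26
hsa-miR-93-3p	-2.2
hsa-let-7g-5p	-2.14
hsa-miR-92a-3p	-2.14
hsa-let-7d-3p	-2.12
hsa-miR-25-3p	-2.07
hsa-miR-423-5p	-2.02
hsa-miR-191-5p	-2.02
hsa-miR-378a-3p	-2.02
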