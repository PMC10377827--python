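# Default serum/plasma miRNA qPCR array panel: 372 targets, 6 endogenous
# controls, 1 exogenous spike-in. Target IDs beginning with 'syn-miR-' are
# synthetic placeholders padding the panel to its nominal size; the
# commercial array's full assay list is proprietary.
name: serum_plasma_384
targets:
  - hsa-let-7a-3p
  - hsa-let-7a-5p
  - hsa-let-7b-5p
  - hsa-let-7c-5p
  - hsa-let-7d-3p
  - hsa-let-7d-5p
  - hsa-let-7e-5p
  - hsa-let-7f-5p
  - hsa-let-7g-5p
  - hsa-let-7i-5p
  - hsa-miR-1-3p
  - hsa-miR-100-5p
  - hsa-miR-101-3p
  - hsa-miR-106b-5p
  - hsa-miR-10a-5p
  - hsa-miR-10b-5p
  - hsa-miR-1180-3p
  - hsa-miR-1183
  - hsa-miR-1203
  - hsa-miR-1207-5p
  - hsa-miR-1225-3p
  - hsa-miR-1237-3p
  - hsa-miR-1247-5p
  - hsa-miR-125a-5p
  - hsa-miR-126-3p
  - hsa-miR-1260a
  - hsa-miR-1260b
  - hsa-miR-127-3p
  - hsa-miR-1281
  - hsa-miR-1287-5p
  - hsa-miR-1290
  - hsa-miR-1301-3p
  - hsa-miR-1307-3p
  - hsa-miR-130a-3p
  - hsa-miR-130b-3p
  - hsa-miR-130b-5p
  - hsa-miR-132-3p
  - hsa-miR-138-1-3p
  - hsa-miR-139-3p
  - hsa-miR-140-5p
  - hsa-miR-142-5p
  - hsa-miR-144-3p
  - hsa-miR-146a-5p
  - hsa-miR-146b-5p
  - hsa-miR-150-5p
  - hsa-miR-151a-3p
  - hsa-miR-151a-5p
  - hsa-miR-151b
  - hsa-miR-152-3p
  - hsa-miR-1539
  - hsa-miR-154-5p
  - hsa-miR-1587
  - hsa-miR-15a-5p
  - hsa-miR-15b-5p
  - hsa-miR-16-5p
  - hsa-miR-181a-5p
  - hsa-miR-181c-3p
  - hsa-miR-181c-5p
  - hsa-miR-181d-5p
  - hsa-miR-185-5p
  - hsa-miR-186-5p
  - hsa-miR-188-5p
  - hsa-miR-18a-3p
  - hsa-miR-18a-5p
  - hsa-miR-1909-5p
  - hsa-miR-190a-5p
  - hsa-miR-191-5p
  - hsa-miR-1910-5p
  - hsa-miR-1913
  - hsa-miR-192-5p
  - hsa-miR-193a-5p
  - hsa-miR-193b-3p
  - hsa-miR-194-5p
  - hsa-miR-195-5p
  - hsa-miR-1976
  - hsa-miR-199a-5p
  - hsa-miR-199b-3p
  - hsa-miR-199b-5p
  - hsa-miR-19a-3p
  - hsa-miR-19b-3p
  - hsa-miR-206
  - hsa-miR-20b-5p
  - hsa-miR-21-5p
  - hsa-miR-210-3p
  - hsa-miR-2110
  - hsa-miR-219a-1-3p
  - hsa-miR-223-3p
  - hsa-miR-224-5p
  - hsa-miR-2276-3p
  - hsa-miR-23a-3p
  - hsa-miR-24-3p
  - hsa-miR-2467-3p
  - hsa-miR-25-3p
  - hsa-miR-26b-3p
  - hsa-miR-26b-5p
  - hsa-miR-27b-3p
  - hsa-miR-28-3p
  - hsa-miR-28-5p
  - hsa-miR-29b-3p
  - hsa-miR-301a-3p
  - hsa-miR-30a-3p
  - hsa-miR-30e-3p
  - hsa-miR-3131
  - hsa-miR-3135b
  - hsa-miR-3141
  - hsa-miR-3176
  - hsa-miR-3183
  - hsa-miR-3185
  - hsa-miR-3191-3p
  - hsa-miR-3200-5p
  - hsa-miR-320a
  - hsa-miR-320e
  - hsa-miR-324-3p
  - hsa-miR-324-5p
  - hsa-miR-328-3p
  - hsa-miR-330-3p
  - hsa-miR-331-3p
  - hsa-miR-338-3p
  - hsa-miR-339-3p
  - hsa-miR-339-5p
  - hsa-miR-340-5p
  - hsa-miR-342-3p
  - hsa-miR-345-5p
  - hsa-miR-34a-5p
  - hsa-miR-34c-3p
  - hsa-miR-361-3p
  - hsa-miR-361-5p
  - hsa-miR-3610
  - hsa-miR-3622a-5p
  - hsa-miR-363-3p
  - hsa-miR-3646
  - hsa-miR-3651
  - hsa-miR-3653-3p
  - hsa-miR-365b-3p
  - hsa-miR-370-3p
  - hsa-miR-373-5p
  - hsa-miR-374a-5p
  - hsa-miR-374c-5p
  - hsa-miR-375
  - hsa-miR-376c-3p
  - hsa-miR-378a-3p
  - hsa-miR-378a-5p
  - hsa-miR-378b
  - hsa-miR-378e
  - hsa-miR-378g
  - hsa-miR-382-5p
  - hsa-miR-3907
  - hsa-miR-3911
  - hsa-miR-3923
  - hsa-miR-409-3p
  - hsa-miR-421
  - hsa-miR-423-5p
  - hsa-miR-424-3p
  - hsa-miR-425-3p
  - hsa-miR-425-5p
  - hsa-miR-4258
  - hsa-miR-4267
  - hsa-miR-4274
  - hsa-miR-4291
  - hsa-miR-4301
  - hsa-miR-4302
  - hsa-miR-4306
  - hsa-miR-4323
  - hsa-miR-433-3p
  - hsa-miR-4422
  - hsa-miR-4454
  - hsa-miR-4505
  - hsa-miR-4516
  - hsa-miR-451a
  - hsa-miR-4538
  - hsa-miR-454-3p
  - hsa-miR-4651
  - hsa-miR-4687-5p
  - hsa-miR-4688
  - hsa-miR-4689
  - hsa-miR-4732-3p
  - hsa-miR-4732-5p
  - hsa-miR-484
  - hsa-miR-485-5p
  - hsa-miR-487b-3p
  - hsa-miR-489-3p
  - hsa-miR-490-3p
  - hsa-miR-501-5p
  - hsa-miR-502-3p
  - hsa-miR-505-3p
  - hsa-miR-5095
  - hsa-miR-523-5p
  - hsa-miR-548o-5p
  - hsa-miR-550a-5p
  - hsa-miR-574-3p
  - hsa-miR-590-5p
  - hsa-miR-596
  - hsa-miR-598-3p
  - hsa-miR-605-5p
  - hsa-miR-625-3p
  - hsa-miR-627-5p
  - hsa-miR-628-3p
  - hsa-miR-629-5p
  - hsa-miR-664a-3p
  - hsa-miR-671-3p
  - hsa-miR-675-3p
  - hsa-miR-7-1-3p
  - hsa-miR-7-2-3p
  - hsa-miR-7-5p
  - hsa-miR-769-5p
  - hsa-miR-874-3p
  - hsa-miR-877-3p
  - hsa-miR-877-5p
  - hsa-miR-92a-3p
  - hsa-miR-92b-3p
  - hsa-miR-93-3p
  - hsa-miR-93-5p
  - hsa-miR-942-5p
  - hsa-miR-99a-5p
  - syn-miR-0001
  - syn-miR-0002
  - syn-miR-0003
  - syn-miR-0004
  - syn-miR-0005
  - syn-miR-0006
  - syn-miR-0007
  - syn-miR-0008
  - syn-miR-0009
  - syn-miR-0010
  - syn-miR-0011
  - syn-miR-0012
  - syn-miR-0013
  - syn-miR-0014
  - syn-miR-0015
  - syn-miR-0016
  - syn-miR-0017
  - syn-miR-0018
  - syn-miR-0019
  - syn-miR-0020
  - syn-miR-0021
  - syn-miR-0022
  - syn-miR-0023
  - syn-miR-0024
  - syn-miR-0025
  - syn-miR-0026
  - syn-miR-0027
  - syn-miR-0028
  - syn-miR-0029
  - syn-miR-0030
  - syn-miR-0031
  - syn-miR-0032
  - syn-miR-0033
  - syn-miR-0034
  - syn-miR-0035
  - syn-miR-0036
  - syn-miR-0037
  - syn-miR-0038
  - syn-miR-0039
  - syn-miR-0040
  - syn-miR-0041
  - syn-miR-0042
  - syn-miR-0043
  - syn-miR-0044
  - syn-miR-0045
  - syn-miR-0046
  - syn-miR-0047
  - syn-miR-0048
  - syn-miR-0049
  - syn-miR-0050
  - syn-miR-0051
  - syn-miR-0052
  - syn-miR-0053
  - syn-miR-0054
  - syn-miR-0055
  - syn-miR-0056
  - syn-miR-0057
  - syn-miR-0058
  - syn-miR-0059
  - syn-miR-0060
  - syn-miR-0061
  - syn-miR-0062
  - syn-miR-0063
  - syn-miR-0064
  - syn-miR-0065
  - syn-miR-0066
  - syn-miR-0067
  - syn-miR-0068
  - syn-miR-0069
  - syn-miR-0070
  - syn-miR-0071
  - syn-miR-0072
  - syn-miR-0073
  - syn-miR-0074
  - syn-miR-0075
  - syn-miR-0076
  - syn-miR-0077
  - syn-miR-0078
  - syn-miR-0079
  - syn-miR-0080
  - syn-miR-0081
  - syn-miR-0082
  - syn-miR-0083
  - syn-miR-0084
  - syn-miR-0085
  - syn-miR-0086
  - syn-miR-0087
  - syn-miR-0088
  - syn-miR-0089
  - syn-miR-0090
  - syn-miR-0091
  - syn-miR-0092
  - syn-miR-0093
  - syn-miR-0094
  - syn-miR-0095
  - syn-miR-0096
  - syn-miR-0097
  - syn-miR-0098
  - syn-miR-0099
  - syn-miR-0100
  - syn-miR-0101
  - syn-miR-0102
  - syn-miR-0103
  - syn-miR-0104
  - syn-miR-0105
  - syn-miR-0106
  - syn-miR-0107
  - syn-miR-0108
  - syn-miR-0109
  - syn-miR-0110
  - syn-miR-0111
  - syn-miR-0112
  - syn-miR-0113
  - syn-miR-0114
  - syn-miR-0115
  - syn-miR-0116
  - syn-miR-0117
  - syn-miR-0118
  - syn-miR-0119
  - syn-miR-0120
  - syn-miR-0121
  - syn-miR-0122
  - syn-miR-0123
  - syn-miR-0124
  - syn-miR-0125
  - syn-miR-0126
  - syn-miR-0127
  - syn-miR-0128
  - syn-miR-0129
  - syn-miR-0130
  - syn-miR-0131
  - syn-miR-0132
  - syn-miR-0133
  - syn-miR-0134
  - syn-miR-0135
  - syn-miR-0136
  - syn-miR-0137
  - syn-miR-0138
  - syn-miR-0139
  - syn-miR-0140
  - syn-miR-0141
  - syn-miR-0142
  - syn-miR-0143
  - syn-miR-0144
  - syn-miR-0145
  - syn-miR-0146
  - syn-miR-0147
  - syn-miR-0148
  - syn-miR-0149
  - syn-miR-0150
  - syn-miR-0151
  - syn-miR-0152
  - syn-miR-0153
  - syn-miR-0154
  - syn-miR-0155
  - syn-miR-0156
  - syn-miR-0157
  - syn-miR-0158
endogenous_controls:
  - SNORD61
  - SNORD68
  - SNORD72
  - SNORD95
  - SNORD96A
  - RNU6B
spike_in: cel-miR-39-3p
hemolysis_pair:
  - hsa-miR-23a-3p
  - hsa-miR-451a
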