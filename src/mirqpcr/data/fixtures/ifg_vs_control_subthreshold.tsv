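# Sub-threshold (|FR| < 2) IFG-vs-control fold regulations reported in the
# study narrative for the two T2D-specific candidate miRNAs; the printed
# differential tables list only |FR| >= 2 entries.
mature_id	fold_regulation
hsa-miR-1225-3p	1.9
hsa-miR-146a-5p	-1.3
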