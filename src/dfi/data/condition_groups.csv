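# Companion-condition groups referenced from codes.csv.
# gangrene_companion: 785.4 gangrene counts as foot gangrene only when the
# same record scope also carries diabetes with peripheral circulatory
# disorders (250.7x) or atherosclerosis of native arteries of the
# extremities (440.2x, i.e. any condition classifiable to 440.21-440.23).
condition_group,pattern,system,match_mode
gangrene_companion,2507,ICD9CM_DX,PREFIX
gangrene_companion,4402,ICD9CM_DX,PREFIX
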