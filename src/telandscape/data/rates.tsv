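# Neutral nucleotide substitution rates, substitutions per site per year
budgerigar	2.22e-9
chicken	2.00e-9
turkey	3.56e-9
medium_ground_finch	2.05e-9
zebra_finch	3.44e-9
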