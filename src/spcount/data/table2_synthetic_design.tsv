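run_id	group
cancer_r1	cancer
cancer_r2	cancer
cancer_r3	cancer
fertile_r1	fertile
fertile_r2	fertile
fertile_r3	fertile
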