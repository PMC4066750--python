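grp1_s1	grp1
grp1_s2	grp1
grp1_s3	grp1
grp1_s4	grp1
grp1_s5	grp1
grp2_s6	grp2
grp2_s7	grp2
grp2_s8	grp2
grp2_s9	grp2
grp2_s10	grp2
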