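<param>
p_cutoff=1.000000e-10
p_floor=1.000000e-200
dims=2
</param>
<seq>
>alpha first
ACDEFGHI
>beta
ACDEFGHV
</seq>
<pos>
0 0.123456 0.765432 0.000000
1 -1.500000 2.250000 0.000000
</pos>
<hsp>
0 1:1.500000e-18
</hsp>
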