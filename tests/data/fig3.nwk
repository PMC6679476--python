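(((L1:1,L2:1)t1:1,L3:2)I1:1,(L4:1,L5:1)t2:2,L6:3)R;
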