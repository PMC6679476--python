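#NEXUS
BEGIN TREES;
TREE example = [&R] (((L1[&color=red]:1,L2[&color=gold]:1)[&color=red]:1,L3[&color=gray]:2)[&color=gray]:1,(L4[&color=red]:1,L5[&color=red]:1)[&color=red]:2,L6[&color=gold]:3)[&color=gray];
END;
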