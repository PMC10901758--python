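(((((tgtA:0.10,bg1:0.10):0.06,(tgtB:0.10,bg2:0.10):0.06):0.08,(bg3:0.12,bg4:0.12):0.06):0.10,tgtC:0.30):0.12,outgroup:0.45);
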