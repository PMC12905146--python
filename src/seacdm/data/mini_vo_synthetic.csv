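id,label,parents
VO_9000001,vaccine,
VO_9000002,influenza vaccine,VO_9000001
VO_0001236,trivalent influenza vaccine,VO_9000002
VO_9000003,live attenuated influenza vaccine,VO_9000002
VO_9000004,inactivated influenza vaccine,VO_9000002
VO_9000010,Fluarix,VO_0001236|VO_9000004
VO_9000011,Fluvirin,VO_0001236|VO_9000004
VO_0000047,Fluzone,VO_0001236|VO_9000004
VO_9000012,FluMist,VO_0001236|VO_9000003
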