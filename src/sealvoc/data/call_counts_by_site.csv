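vocal_type,M1,M2,M3,Lehua,Kala,Lalo,Manawai
Croak,5,24,36,1904,6,4535,1702
CroakHumGrowlWhoop,0,0,0,0,0,0,1
Growl,17,60,68,2847,4,5249,2318
GrowlRumble,0,0,1,0,0,0,2
GrowlRumbleWhoop,0,1,4,0,1,3,4
GrowlWhoop,0,4,1,4,0,3,3
HumGrowl,0,0,0,0,0,0,1
HumGrowlRumble,0,0,0,0,0,0,1
HumWhoop,0,1,0,0,0,0,0
Moan,0,1,4,69,2,204,137
MoanGrowl,0,2,4,30,1,132,106
MoanGrowlMoanWhoop,0,1,0,0,0,0,0
MoanGrowlRumble,0,0,0,0,0,0,2
MoanGrowlRumbleWhoop,0,2,1,0,0,0,2
MoanGrowlWhoop,0,0,2,0,0,1,1
MoanHum,0,0,0,0,0,0,2
MoanHumGrowl,0,0,0,0,0,0,26
MoanHumGrowlRumbleWhoop,0,0,0,0,0,0,1
MoanWhine,0,0,0,8,0,0,0
MoanWhoop,0,1,7,12,0,7,4
Rumble,0,0,1,0,1,0,0
RumbleWhoop,0,0,1,0,0,0,0
Whine,0,0,0,1,0,0,0
Whoop,6,110,93,647,5,2043,896
WhoopGrunt,0,0,0,0,0,30,0
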