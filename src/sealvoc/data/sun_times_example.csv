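date,sunrise_local,sunset_local,site
2021-07-23,06:00,19:14,Lalo
2021-07-24,06:00,19:14,Lalo
2021-07-25,06:01,19:13,Lalo
2021-07-26,06:01,19:13,Lalo
2021-07-27,06:02,19:13,Lalo
2021-08-08,06:10,19:05,Manawai
2021-08-09,06:10,19:04,Manawai
2021-08-10,06:11,19:03,Manawai
2021-08-11,06:11,19:03,Manawai
2021-08-12,06:12,19:02,Manawai
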