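subject	muscle	status
01	TU	NO
01	TM	LAT
01	TL	NO
01	DA	NO
01	DM	NO
01	DP	NO
01	PM	NO
01	BS	LAT
01	BL	NO
01	TLA	NO
01	TLO	NO
01	BR	NO
01	SCOM	LAT
02	TU	LAT
02	TM	LAT
02	TL	NO
02	DA	NO
02	DM	NO
02	DP	NO
02	PM	NO
02	BS	NO
02	BL	NO
02	TLA	NO
02	TLO	LAT
02	BR	LAT
02	SCOM	NO
03	TU	NO
03	TM	NO
03	TL	NO
03	DA	ACT
03	DM	NO
03	DP	NO
03	PM	NO
03	BS	NO
03	BL	NO
03	TLA	NO
03	TLO	LAT
03	BR	NO
03	SCOM	NO
04	TU	NO
04	TM	NO
04	TL	NO
04	DA	NO
04	DM	NO
04	DP	NO
04	PM	NO
04	BS	NO
04	BL	NO
04	TLA	NO
04	TLO	NO
04	BR	NO
04	SCOM	NO
05	TU	LAT
05	TM	NO
05	TL	NO
05	DA	NO
05	DM	NO
05	DP	NO
05	PM	LAT
05	BS	NO
05	BL	NO
05	TLA	NO
05	TLO	NO
05	BR	NO
05	SCOM	NO
06	TU	NO
06	TM	NO
06	TL	NO
06	DA	NO
06	DM	NO
06	DP	LAT
06	PM	LAT
06	BS	NO
06	BL	NO
06	TLA	NO
06	TLO	NO
06	BR	NO
06	SCOM	NO
07	TU	LAT
07	TM	ACT
07	TL	NO
07	DA	NO
07	DM	NO
07	DP	NO
07	PM	LAT
07	BS	LAT
07	BL	NO
07	TLA	NO
07	TLO	LAT
07	BR	NO
07	SCOM	LAT
08	TU	LAT
08	TM	LAT
08	TL	NO
08	DA	NO
08	DM	NO
08	DP	LAT
08	PM	LAT
08	BS	LAT
08	BL	NO
08	TLA	NO
08	TLO	LAT
08	BR	LAT
08	SCOM	LAT
09	TU	NO
09	TM	NO
09	TL	NO
09	DA	NO
09	DM	LAT
09	DP	LAT
09	PM	LAT
09	BS	LAT
09	BL	NO
09	TLA	LAT
09	TLO	LAT
09	BR	LAT
09	SCOM	LAT
10	TU	LAT
10	TM	NO
10	TL	NO
10	DA	NO
10	DM	NO
10	DP	LAT
10	PM	LAT
10	BS	NO
10	BL	NO
10	TLA	LAT
10	TLO	LAT
10	BR	NO
10	SCOM	ACT
11	TU	NO
11	TM	NO
11	TL	NO
11	DA	NO
11	DM	NO
11	DP	NO
11	PM	NO
11	BS	NO
11	BL	NO
11	TLA	NO
11	TLO	NO
11	BR	NO
11	SCOM	ACT
12	TU	NO
12	TM	NO
12	TL	NO
12	DA	NO
12	DM	NO
12	DP	NO
12	PM	NO
12	BS	NO
12	BL	NO
12	TLA	NO
12	TLO	NO
12	BR	NO
12	SCOM	ACT
13	TU	NO
13	TM	NO
13	TL	NO
13	DA	LAT
13	DM	NO
13	DP	NO
13	PM	ACT
13	BS	LAT
13	BL	LAT
13	TLA	ACT
13	TLO	ACT
13	BR	ACT
13	SCOM	LAT
14	TU	LAT
14	TM	ACT
14	TL	LAT
14	DA	NO
14	DM	ACT
14	DP	NO
14	PM	LAT
14	BS	LAT
14	BL	NO
14	TLA	NO
14	TLO	ACT
14	BR	NO
14	SCOM	ACT
15	TU	NO
15	TM	LAT
15	TL	NO
15	DA	NO
15	DM	NO
15	DP	NO
15	PM	NO
15	BS	LAT
15	BL	LAT
15	TLA	NO
15	TLO	LAT
15	BR	NO
15	SCOM	NO
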