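symbol	chromosome	start	end	reference_copies	assay_group	orthologue
DEFB43	chr8	7449722	7456717	1	DEFB43	HBD131A
DEFB134	chr8	7469680	7473928	1	DEFB134	HBD134
DEFB136	chr8	7499869	7500896	1	DEFB136	HBD136
DEFB132-1	chr13	60755471	60757652	1	DEFB132-1	HBD132
DEFB129-2	chr13	60772966	60775142	1	DEFB129-2	HBD129
DEFB128	chr13	60785898	60787480	1	DEFB128	HBD128
DEFB127	chr13	60793742	60796520	1	DEFB127	HBD127
DEFB126	chr13	60806515	60811042	1	DEFB126	HBD126
DEFB125A	chr13	60828555	60835043	1	DEFB125A	HBD125
DEFB125	chr13	60828987	60829208	1	DEFB125	HBD125
DEFB115	chr13	60873647	60884399	1	DEFB115	HBD115
DEFB29	chr13	60893940	60905009	1	DEFB29
DEFB116	chr13	60920317	60925563	1	DEFB116	HBD116
DEFB117	chr13	60956394	60959265	1	DEFB117	HBD118
DEFB118	chr13	60979467	60979700	1	DEFB118	HBD118
DEFB119-1	chr13	60981163	60990988	1	DEFB119-1	HBD119
DEFB119-2	chr13	60989366	60990988	1	DEFB119-2
DEFB121	chr13	61007870	61009276	1	DEFB121	HBD121
DEFB122A	chr13	61019572	61023625	1	DEFB122A
DEFB122	chr13	61030365	61034955	1	DEFB122
DEFB123-2	chr13	61038268	61052092	1	DEFB123-2	HBD123
DEFB123-1	chr13	61041375	61051806	1	DEFB123-1	HBD123
DEFB124	chr13	61067234	61069998	1	DEFB124	HBD124
DEFB114	chr23	22612721	22615376	1	DEFB114	HBD114
DEFB113	chr23	22632551	22635067	1	DEFB113	HBD113
DEFB110-1	chr23	22644099	22656635	1	DEFB110-1	HBD110
DEFB110-2	chr23	22651406	22656635	1	DEFB110-2
DEFB112	chr23	22662983	22671406	1	DEFB112	HBD112
DEFB1-2	chr27	5960716	5968525	1	DEFB1-2
TAP	chr27	6013830	6015648	1	TAP
DEFB103B	chr27	6023993	6025303	3	DEFB103	HBD103B/HBD-like
SPAG11B	chr27	6045534	6050941	1	SPAG11B	H-SPAG11B
DEFB104	chr27	6069928	6074858	1	DEFB104	HBD104A
DEFB106A	chr27	6076779	6079838	1	DEFB106A	HBD106B-2
DEFB15	chr27	6076989	6079896	1	DEFB15	HBD106B-2
DEFB105	chr27	6082209	6084799	1	DEFB105	HBD105A
DEFB107A	chr27	6090910	6095691	1	DEFB107A	HBD107A/HBD106B-1
DEFB130-1	chr27	6192946	6196744	1	DEFB130-1	HBD130A
LAP	chr27	6234006	6235870	1	LAP
DEFB33	chr27	6238997	6242941	1	DEFB33
DEFB13	chr27	6326696	6328616	1	DEFB13
DEFB103A	chr27	6432334	6433571	3	DEFB103	HBD103B/HBD-like
DEFB10	chr27	6596623	6598299	1	DEFB10
DEFB3	chr27	6676309	6723692	1	DEFB3
DEFB7	chr27	6676383	6678273	1	DEFB7
DEFB6	chr27	6676387	6996057	1	DEFB6
DEFB9	chr27	6676540	6678161	1	DEFB9
DEFB1-1	chr27	6721772	6723692	1	DEFB1-1	HBD1
DEFB402	chr27	6855327	6856946	1	DEFB402
DEFB4A	chr27	7138963	7140882	1	DEFB4A
DEFB5	chr27	7139081	7140848	1	DEFB5
EBD	chr27	7165176	7180422	1	EBD
DEFB108B	chr27	7272455	7275948	1	DEFB108B	HBD108B
DEFB109	chr27	7281838	7289252	1	DEFB109	HBD109
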