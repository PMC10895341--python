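study	group	n	n_male	n_female	n_hla_noncarrier	n_hla_carrier	birth_year_mean	birth_year_sd	giv_jiang_mean	giv_jiang_sd	giv_revez_mean	giv_revez_sd
KPNC	case	1084	215	869	506	578	1957.6	8.9	0.285	0.07	2.150	0.12
KPNC	control	10956	2165	8791	8280	2676	1957.1	8.6	0.288	0.07	2.163	0.19
UKB	case	2087	576	1511	1050	1037	1952.7	7.6	0.292	0.07	2.184	0.19
UKB	control	20870	5760	15110	15271	5599	1952.7	7.6	0.293	0.07	2.187	0.19
GSA	case	3718	1031	2687	1621	2097	1973.1	12.4	0.289	0.07	2.057	0.19
GSA	control	1180	342	838	843	336	1968.9	13.7	0.293	0.07	2.074	0.18
OMNI	case	6709	1808	4901	2913	3796	1961.0	13.7	0.286	0.07	2.066	0.19
OMNI	control	5881	1455	4426	4052	1829	1960.5	13.3	0.290	0.07	2.070	0.19
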