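genome_id	subclade	n_contigs	genome_size_bp	n_proteins	longest_contig_bp	n50_bp	gc_percent	completeness	contamination
NPMR_NP_delta_1	NP-delta	83	1173997	1467	79876	28788	34.08	86.2	5.4
NPMR_NP_delta_2	NP-delta	270	610368	870	12327	3054	33.9	67.9	0.7
NPMR_NP_delta_3	NP-delta	143	937620	1222	58541	15484	34.2	66.3	3.4
NPMR_NP_theta_1	NP-theta	176	1524500	2000	40454	14847	35	99.5	2.9
NPMR_NP_theta_2	NP-theta	298	1201755	1671	26499	5123	35	93.7	4
YK1312_12N_NP_theta	NP-theta	299	1221321	1695	20455	5469	34	88.8	5.3
NPMR_NP_theta_3	NP-theta	552	1069514	1706	14642	2738	34.4	83.6	3.9
NPMR_NP_theta_4	NP-theta	232	1040901	1408	21324	6332	34	76.2	6.3
NPMR_NP_theta_5	NP-theta	274	697980	970	14641	3916	35.1	75	1.2
NPMR_NP_iota_1	NP-iota	68	1121898	1402	75887	30338	35.8	98.5	1
YK1309_1N_NP_iota	NP-iota	227	1298549	1700	40725	9447	35.8	96.6	3.2
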