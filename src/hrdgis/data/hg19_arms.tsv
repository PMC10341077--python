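chromosome	length	centromere_start	centromere_end	p_telomere_assembled	q_telomere_assembled
chr1	249250621	121535435	124535434	true	true
chr2	243199373	92326172	95326171	true	true
chr3	198022430	90504855	93504854	true	true
chr4	191154276	49660118	52660117	true	true
chr5	180915260	46405642	49405641	true	true
chr6	171115067	58830167	61830166	true	true
chr7	159138663	58054332	61054331	true	true
chr8	146364022	43838888	46838887	true	true
chr9	141213431	47367680	50367679	true	true
chr10	135534747	39254936	42254935	true	true
chr11	135006516	51644206	54644205	true	true
chr12	133851895	34856695	37856694	true	true
chr13	115169878	16000001	19000000	false	true
chr14	107349540	16000001	19000000	false	true
chr15	102531392	17000001	20000000	false	true
chr16	90354753	35335802	38335801	true	true
chr17	81195210	22263007	25263006	true	true
chr18	78077248	15460899	18460898	true	true
chr19	59128983	24681783	27681782	true	true
chr20	63025520	26369570	29369569	true	true
chr21	48129895	11288130	14288129	false	true
chr22	51304566	13000001	16000000	false	true
chrX	155270560	58632013	61632012	true	true
chrY	59373566	10104554	13104553	true	true
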