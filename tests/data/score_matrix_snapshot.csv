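mirna_id,circ_id,s_affinity,s_nbmre,s_enrichmre,s_fc_circ,s_mirexpr,s_targetexpr_circ,s_enrichsg,ss,rank_global,condition,rank_in_condition,n_mrna_targets,mean_sg_of_targets,mrna_target_list
hsa-miR-100-5p,hsa_circ_0000001,1.0,0.035555555555555556,5.4511740691572664e-08,4.981681967103615,12.035896105055734,14.157708624078618,0.012121212121212121,1.0,1,condition_2,1,4,0.9849767199419764,GENE0001;GENE0002;GENE0003;GENE0004
hsa-miR-113-5p,hsa_circ_0000003,0.40511856633113913,0.0015174506828528073,0.02636298772727698,1.2480452988968729,6.550796768536479,9.842864489002471,0.20606060606060606,0.2273005709359703,2,condition_2,2,3,0.3626210399687455,GENE0001;GENE0067;GENE0068
hsa-miR-103-5p,hsa_circ_0000005,0.38639431422710485,0.004366812227074236,0.02636298772727698,-1.485749853561142,3.0840644377384514,5.524366313043217,0.12121212121212122,0.20859577364878804,3,condition_1,1,1,0.06398739695328531,GENE0021
hsa-miR-103-5p,hsa_circ_0000040,0.31359451464996785,0.007692307692307693,0.018037179907789625,-0.3691508727260846,3.0840644377384514,4.723284606631382,0.12121212121212122,0.19584117791075542,4,condition_1,2,1,0.06398739695328531,GENE0021
hsa-miR-103-5p,hsa_circ_0000015,0.43564200212853793,0.002678093197643278,0.02636298772727698,-0.7174835935749249,3.0840644377384514,6.984180584196647,0.12121212121212122,0.1926666026054929,5,condition_1,3,1,0.06398739695328531,GENE0021
hsa-miR-107-5p,hsa_circ_0000014,0.15744760528236657,0.00165929203539823,0.02636298772727698,1.074466821795716,2.3651427589453458,7.720003178796591,0.12121212121212122,0.16757171000374566,6,condition_2,3,3,0.2612739964532216,GENE0001;GENE0072;GENE0076
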