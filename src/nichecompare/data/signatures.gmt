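core_identity_79	embryonic cortical RP / V-SVZ NSC core identity (63 enriched + 16 companion genes)	Acaa2	Aldoc	Apoe	Asrgl1	Ccdc80	Cd63	Ckb	Cyr61	Dbi	Ddah1	Efhd2	Fabp7	Fgfbp3	Gas1	Gng12	Gpx8	Gsta4	Hes1	Hes5	Hopx	Id1	Id3	Id4	Lfng	Magt1	Mdk	Mfge8	Mlc1	Mt1	Mt2	Mt3	Myo10	Nek6	Nes	Nr2e1	Nrarp	Oat	Pax6	Pdpn	Pea15a	Phgdh	Pon2	Psat1	Ptprz1	Rcn1	Rhoc	Serpinh1	Sfrp1	Slc1a3	Slc9a3r1	Sox2	Sox21	Sox9	Sparc	Tead2	Tfap2c	Tgfb2	Tnc	Ttyh1	Vcam1	Veph1	Vim	Zfp36l1	NdeI	Rgcc	Ednrb	Metrn	Kbtbd11	Gm11627	Acadl	Aldhl11	Bcan	Vit	Acss1	Acsbg1	Atp1a2	Clu	Pnp	Rcn3
astrocyte_26	niche-astrocyte signature distinguishing astrocytes from NSCs in both niches	Aqp4	Slc4a4	Gjb6	Grin2c	Abhd3	Cxcl14	S100b	Fgfr3	Cadm2	Slc39a12	Tril	Hapln1	Arxes2	Gabrg1	Car2	Pfkp	Lcat	Hsd11b1	Cryab	Vegfa	Timp4	AI464131	Omg	Syne1	Cd38	Agt
shared_dormant_94	shared adult dormant NSC signature (enriched vs embryonic RPs and vs adult TAPs/IPs in both niches)	2310022B05Rik	4930402H24Rik	Acsbg1	Acsl6	Aldoc	Apoe	Arhgap5	Atp1a2	Atp1b2	Bhlhe41	Chchd10	Clu	Cmtm5	Cpe	Cspg5	Csrp1	Cst3	Cxcl14	Dbp	Dclk1	Dtna	Entpd2	Fam107a	Fxyd1	Gabrb1	Gfap	Gja1	Gm10561	Gm2a	Gm3764	Gnao1	Gpm6a	Gpm6b	Gpr37l1	Gstm1	Hepacam	Id4	Itih3	Itm2c	Kcnj10	Lsamp	Malat1	Mfge8	Mgll	Mlc1	Mmd2	Msi2	Mt1	Mt2	Mt3	Neat1	Nrxn1	Nrxn2	Ntm	Ntrk2	Ntsr2	Ogt	Phkg1	Pitpnc1	Pla2g7	Plpp3	Prex2	Prnp	Psap	Ptprz1	Qk	Ramp1	Riiad1	Rsrp1	S100a1	S100a16	S100a6	S1pr1	Scarb2	Scd2	Scg3	Sdc4	Selm	Sepp1	Sfxn5	Sirpa	Slc1a2	Slc1a3	Slc6a1	Slc6a11	Sox9	Sparcl1	Syt11	Timp3	Tmem47	Tpcn1	Tsc22d4	Tspan7	Ttyh1
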