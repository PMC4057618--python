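human_acc	yeast_acc
Q9GZR2	Q08237
Q9P2J9	Q12511
Q15067	P13711
P49247	Q12189
Q9BZP6	Q06350
Q96S44	P53323
Q9UBZ4	P38207
O60825	P32604
O95154	P42884
Q14410	P32190
O15305	P07283
P78368	P23292
P51659	Q02207
Q9UNI6	Q02256
Q6PI48	P15179
P20618	P23724
Q96RR4	P43637
Q13164	Q00772
Q96T52	P46972
Q9NUW8	P38319
P06744	P12709
P08397	P28789
P00480	P05150
P11498	P32327
P04424	P04076
Q6IA69	P38795
P05186	P11491
P40818	P32571
Q04760	P50107
Q8TF76	P32789
Q8IWW8	P10127
P36873	P32598
P29120	P13134
P37268	P29704
Q9P2K8	P15442
Q8IWX5	P23501
Q96G46	Q06053
Q96GX9	P47095
Q96DP5	P32785
P48637	Q08220
Q13332	P25044
Q9Y3E5	P34222
P09467	P09201
P12955	P43590
P25789	P23638
Q9UGM6	P04803
P06132	P32347
P60484	P53916
P78549	P31378
O75191	P42826
P49917	Q08387
O96017	P39009
Q9H3S4	P35202
P32320	Q06549
Q7L3T8	P39965
P06737	P06738
Q9NSY1	P53974
Q9NYY3	P32562
Q13907	P15496
O60942	Q01159
O43426	P50942
P49841	P38615
Q9UGP5	P25615
O95363	P08425
P36871	P37012
Q9BUP3	P40008
P34949	P29952
Q9UBZ9	P12689
P54098	P15801
Q7L211	P42840
Q9HBY8	P12688
Q9UJM8	P00175
P07741	P49435
P07902	P08431
Q8WUX2	P32656
P13716	P05373
Q9Y2L1	Q08162
Q14249	P08466
P48449	P38604
Q96C11	Q04585
Q5VTY9	Q08929
P49336	P39073
O14818	P40303
Q86YJ6	P16120
Q8IZ73	Q12362
O00743	P20604
P12081	P07263
Q69YN2	P53255
Q5T2R2	P18900
Q9UQB9	P38991
Q99447	P33412
P04180	P40345
O14734	P41903
P30793	P51601
Q9Y3Q0	P47161
P14550	P14065
Q9BV23	P53750
O43175	P40054
P08243	P49090
P56937	Q12452
P22830	P16622
Q86V88	P40081
Q16769	P43599
O95336	P38858
Q8IXB1	P40564
Q15386	P53119
Q969P6	P04786
Q9Y3B8	P54964
Q9Y2H1	P53894
Q9Y2Z4	P48527
P00813	P53909
Q9UI42	P38836
Q9Y6R4	P53599
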