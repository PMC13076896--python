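channel	CN1	CN9	CN24	CNV48B
0:homdel:0-100kb	0.0024119838991198215	0.0024035936714481175	0.002257934476538803	0.0003975300428907564
0:homdel:100kb-1Mb	0.0030378897907271177	0.0013808624446466893	0.0003748824969182524	0.0017240056756634206
0:homdel:>1Mb	0.0010636262720004506	0.0002732416672060097	0.0015752875335494844	0.0008127681150785671
1:LOH:0-100kb	0.010121511180293308	0.002341713294097103	0.011011146563509258	0.03754816878352622
1:LOH:100kb-1Mb	0.0020900166708285365	9.767214260764613e-05	0.0024024070471396217	0.08485059115535831
1:LOH:1Mb-10Mb	4.987155706968296e-05	0.0008361850201033855	0.001517312371331771	0.14954666418869544
1:LOH:10Mb-40Mb	0.0031907597958403507	0.00353283583270627	0.008305705774858797	0.17207373426446682
1:LOH:>40Mb	0.00010707448715089449	0.003310868628194895	0.0007983297427223691	0.12467918904174517
2:LOH:0-100kb	0.0024861789982099577	0.04590176341365574	0.000500847008988864	0.024762258755540615
2:LOH:100kb-1Mb	0.0017369944393772056	0.09090945510073568	0.001952717654679069	0.0483902214345518
2:LOH:1Mb-10Mb	0.0012787850095183012	0.13763338277500986	0.0009227997348852807	0.09488822684053969
2:LOH:10Mb-40Mb	0.0013311470584907617	0.09174587137939519	0.0021428029711740683	0.11353047739988455
2:LOH:>40Mb	0.0005638351622594848	0.05117512780774461	0.0019489053686706686	0.07940730979459432
3-4:LOH:0-100kb	0.0006173094246699922	0.001112812670711272	0.0572823308556946	0.0017710886183932453
3-4:LOH:100kb-1Mb	0.0038441446666188112	0.001047085554226224	0.10546318482286828	0.005967296756900768
3-4:LOH:1Mb-10Mb	0.002642653321036874	0.0026251067422143467	0.12528910249222733	0.0006896100445885843
3-4:LOH:10Mb-40Mb	0.0017998421801191907	0.0020641816534070867	0.06360928196912494	0.00033235101889149887
3-4:LOH:>40Mb	0.0010713723453654041	0.004303734248115875	0.033043354241904334	0.005731890155538371
5-8:LOH:0-100kb	0.00065696433162749	0.0030031506009129626	0.0026539594568312412	0.0003876838227832564
5-8:LOH:100kb-1Mb	0.0007470388671802289	0.00018454576164142405	0.001798248078879731	0.0013342602403374692
5-8:LOH:1Mb-10Mb	4.567913499203949e-05	0.004737433424482803	0.0019240545060621556	0.0010736433060941054
5-8:LOH:10Mb-40Mb	0.0012784869002189858	0.0029293209906548954	0.006576108892228953	0.0021332051203060364
5-8:LOH:>40Mb	0.0065600044949581425	0.0029166279866709097	0.002102761512239216	0.0038659564837796095
9+:LOH:0-100kb	0.0021431826813639236	0.0049922991280227065	0.003744033875463837	0.0002091958698629406
9+:LOH:100kb-1Mb	0.0013437987323564086	0.001189564196891296	0.00026490623282114087	0.004087364206850396
9+:LOH:1Mb-10Mb	0.0016719378905800883	0.001439288517017493	0.00014901844622767376	0.0014488293411906545
9+:LOH:10Mb-40Mb	0.0032642030273027714	0.0016241540735998845	0.0020865770750507075	0.0005644866636840303
9+:LOH:>40Mb	0.000924807306451257	0.0002752154419146802	0.0019365968464273092	0.0036627188842937486
2:het:0-100kb	0.02011411345636114	0.0027888054013651773	0.00010043494492983698	0.004779652262887424
2:het:100kb-1Mb	0.05259360686924474	0.0031004933277842465	0.00279297682301619	0.002312802199538611
2:het:1Mb-10Mb	0.13554445977618385	3.132979058733396e-05	0.0008222274220982229	0.00020661567704515765
2:het:10Mb-40Mb	0.25290892999506337	0.0058470181433987935	0.0023846734267633754	0.004993923222017071
2:het:>40Mb	0.45130131622068526	0.004357468602711762	0.0016722728411945635	0.0013610215378957486
3-4:het:0-100kb	0.003490392226319711	0.04667016636297693	0.005402272362196034	0.000771358007373649
3-4:het:100kb-1Mb	0.00038250332119502107	0.09131192305039836	0.001424868469032231	0.0021050943845994153
3-4:het:1Mb-10Mb	0.004004050052664347	0.1598009128288679	0.0019373868214895883	0.00017971101647443758
3-4:het:10Mb-40Mb	0.005043408688201529	0.11600243096980466	0.002037174258040096	0.002512886520737783
3-4:het:>40Mb	0.0012444959057121392	0.06878240639057126	0.0038493444822739423	0.0003651033846730935
5-8:het:0-100kb	0.001522623072826323	7.007114254848146e-05	0.08337337089691123	0.0017100612771938643
5-8:het:100kb-1Mb	0.002596256730093835	0.0010677572645652839	0.1460385369714494	0.003404010309375039
5-8:het:1Mb-10Mb	0.004399799583383874	0.00012330359955055968	0.1672854231597282	0.000705546771464875
5-8:het:10Mb-40Mb	0.0003525852395619506	0.011264233005046215	0.08348565855561542	0.0005907774678646349
5-8:het:>40Mb	0.0016088780188095592	0.0015424490085379546	0.045189024952957874	0.0015946541997431478
9+:het:0-100kb	0.000595203505181622	0.0040453952338895234	0.00021476613860450458	0.0025372924811192556
9+:het:100kb-1Mb	0.0001852514192111416	0.0010836148676819772	0.00018374741589514284	0.0007626622313049614
9+:het:1Mb-10Mb	0.0008093751961732416	0.005652548663700959	0.0028214189458915426	0.0031092090306448616
9+:het:10Mb-40Mb	0.003006573301615706	0.004502976215039125	0.0024781670274045676	1.8586884499288944e-05
9+:het:>40Mb	0.00021507779578416633	0.005967601962938403	0.002871656035490292	0.00010830510751722516
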