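"x","1","2","3"
10.085972,0.41956419113137,0.449534273823139,-0.219270399968232
9.653336,0.397381253218579,0.460592127546309,-0.232969952663517
6.673213,0.204663290256054,0.540514301791097,-0.307904912485676
9.53412,0.390901785141287,0.463722961305243,-0.23662992671849
-9.739562,-0.0209888206137132,0.0499964397438389,-0.0289682225844251
19.346365,0.412321084860152,0.341419393086081,0.2013119203851
10.017444,0.416196564113117,0.451250219099687,-0.221483306792421
8.555907,0.332697763173151,0.490260285060331,-0.264691273275904
8.388161,0.321955097724039,0.494885874755286,-0.269136733234293
7.639608,0.272048667054588,0.515383796306779,-0.287592726462024
1.691784,-0.0835339402541451,0.585035239649129,-0.338972757434731
17.807757,0.466595557349891,0.345161564696069,0.117497454875198
17.656138,0.471020932458714,0.345777657668301,0.109480479906926
-2.535732,-0.149716798481558,0.463682269781467,-0.268660153968988
3.019244,-0.0279345353564117,0.59331259589144,-0.343768704891517
5.767654,0.141060162744473,0.561295702626886,-0.323091745824229
28.772633,-0.161108711172017,0.383050161088588,0.778058550083429
3.845118,0.0164572809131495,0.590019471421383,-0.341827635104541
3.299453,-0.0137032173384851,0.592922215890405,-0.343542413416708
3.006937,-0.0285390044059319,0.593312103161266,-0.343768419400842
7.675735,0.2745180563552,0.51440705732724,-0.286755118267554
2.944927,-0.0315585290984338,0.59328721746787,-0.343754000488032
22.388542,0.262355951513001,0.345449499600788,0.378231367463605
2.603321,-0.047418392208744,0.59248674226841,-0.343290200588078
9.372347,0.381874598327325,0.468019042354974,-0.241515095246096
10.687774,0.446609431769794,0.435135295397767,-0.199163461352689
10.159539,0.423115196590907,0.447708730149873,-0.216877080893121
13.837371,0.51832520157224,0.378486376150739,-0.0755943678952578
-6.824352,-0.0948181935745634,0.236026155043465,-0.136754901550519
15.467481,0.514183411194093,0.360223012589786,-0.00080631354880662
10.321985,0.430714800329571,0.443741733276638,-0.211528042073135
10.017416,0.416195176486552,0.45125092317945,-0.221484207704318
11.084979,0.461990712560908,0.426293050011154,-0.185243709213307
7.096727,0.234432999762498,0.529779806963927,-0.299507701365909
-3.261323,-0.14727167428348,0.431027652579075,-0.249739882358155
21.753867,0.29762987883256,0.343540237151889,0.340274520584585
-10.499713,0,0,0
-2.041434,-0.149382034503188,0.48421395198347,-0.28055632783872
18.797307,0.433575099035634,0.342249430905417,0.170907215443955
0.304595,-0.122354745633981,0.559868157546253,-0.324390806401979
5.653226,0.133125272584561,0.563657880935732,-0.324732800204881
7.596171,0.269073034695061,0.51655562128629,-0.288592529462386
19.590248,0.402248511782432,0.341220021699479,0.214983127371047
1.867288,-0.0772625319306032,0.587054315277455,-0.34014262137936
15.185937,0.516714107860033,0.362890917342599,-0.0141999700521801
10.94039,0.456615491155327,0.429451795957914,-0.190369489129421
8.189866,0.309024714845347,0.500351300392252,-0.274247841985065
17.968303,0.461721228480903,0.344559681065249,0.126035919740855
16.981407,0.48855575189131,0.349097877630079,0.0743704003566103
-0.165349,-0.131427530867466,0.547847998352422,-0.317426257549877
4.557049,0.0598932901942975,0.582399763370531,-0.337133836329225
1.248228,-0.097985989592769,0.578734847025651,-0.335322273983884
1.600578,-0.086668032185227,0.583878847669648,-0.338302737320737
0.196969,-0.124606649272045,0.557264436012912,-0.322882195282624
11.076728,0.461690817503473,0.426471470796729,-0.185538009642244
-1.398419,-0.146329344760121,0.508680757827917,-0.294732534809921
11.094094,0.462321050885473,0.426096203244451,-0.184918339139217
0.334787,-0.121704160132031,0.560582409648771,-0.324804648147374
16.217324,0.503956028529335,0.35405199021046,0.0357810073749804
-6.079126,-0.110304129047071,0.280679712999075,-0.16262742792784
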