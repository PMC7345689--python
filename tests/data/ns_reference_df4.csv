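"x","1","2","3","4"
10.085972,0.653428454227047,0.292028575035274,0.106761733324777,-0.053810115275255
9.653336,0.693278384953272,0.256021874519308,0.0958805015201799,-0.0498545455845018
6.673213,0.794503450494076,0.0190790882062962,0.121356071930935,-0.0656463744027089
9.53412,0.703713504855651,0.245921286108374,0.0932444074767985,-0.0488183206605682
-9.739562,8.95782339490238e-05,-0.0257164352244001,0.056019790114967,-0.0303033548905669
19.346365,0.0843266077857497,0.454237445270629,0.297306418755378,0.164129528188243
10.017444,0.659906312160204,0.28641026549765,0.104921743242661,-0.0531792821370877
8.555907,0.774814574220665,0.162476873738038,0.0803821786889887,-0.0433864232455886
8.388161,0.783574913839631,0.148414453292786,0.08016943921711,-0.043329587967571
7.639608,0.806110937885785,0.0883650997927228,0.0885125551333901,-0.0478799967828042
1.691784,0.369550667354091,-0.194715332627017,0.424161123839664,-0.229445791212647
17.807757,0.132726137171523,0.500728147599169,0.27784562139668,0.0887000938326277
17.656138,0.138308512936348,0.504027603801974,0.275710631360503,0.0819532519011753
-2.535732,0.103013354161667,-0.209051927395739,0.455391464394218,-0.246339536998479
3.019244,0.500313107013997,-0.160404994056975,0.35186301191356,-0.19033683812449
5.767654,0.749709615970304,-0.0373951968882198,0.169097115506327,-0.0914714227176365
28.772633,0,-0.16518012419222,0.359822650677206,0.805357473515013
3.845118,0.584724159486944,-0.130931091819123,0.297017579236702,-0.160668740348282
3.299453,0.529153082773892,-0.151112516680493,0.333771201859889,-0.180550251285375
3.006937,0.499047405190981,-0.160796573840596,0.352641382538569,-0.190757890064128
7.675735,0.805689905748902,0.0911382622322417,0.0877405125727649,-0.047462367947401
2.944927,0.492674370752902,-0.162748455005032,0.356540288335369,-0.192866964835791
22.388542,0.0261964527483613,0.303078329189108,0.325744833969038,0.344980384093492
2.603321,0.457803596548958,-0.172870989206821,0.377253692122378,-0.204071677039481
9.372347,0.717385639443395,0.232138012773255,0.0899740316835166,-0.0474926551060916
10.687774,0.595287778461271,0.339395927868483,0.124077237044135,-0.0588620057930122
10.159539,0.646422911165838,0.298016817407115,0.108776604252214,-0.0544820635957907
13.837371,0.335416032580208,0.498028358607968,0.206835695638182,-0.0402800868263576
-6.824352,0.0101251832124886,-0.118607361141475,0.25837015975415,-0.139762798612675
15.467481,0.237139992628335,0.522881139052545,0.240014468357102,-3.56000379821362e-05
10.321985,0.63080528806988,0.31106455456089,0.113350587479669,-0.0559308924852138
10.017416,0.659908948598601,0.286407962359666,0.10492099918013,-0.053179023780013
11.084979,0.557129279804883,0.368113944985949,0.135907461561355,-0.0611506863709449
7.096727,0.804766716127442,0.0482859827703058,0.104249197673547,-0.0563925789024748
-3.261323,0.0773443901166358,-0.199636743188998,0.434881753831575,-0.235245010642578
21.753867,0.0348118875373918,0.34015175869929,0.320750467500655,0.304285886262663
-10.499713,0,0,0,0
-2.041434,0.123409587824771,-0.213744893610421,0.465614459147149,-0.251869565536728
18.797307,0.0999370611020022,0.473447103969296,0.290805702544513,0.135810132384189
0.304595,0.25721349527264,-0.214134085466514,0.466462261181237,-0.252328175714724
5.653226,0.742151277331399,-0.0439579191787015,0.175984870827341,-0.0951972862644957
7.596171,0.806529565898897,0.085048390244304,0.0894886092678548,-0.0484079836740152
19.590248,0.0779492201881875,0.444827255230966,0.300045197855511,0.177178326725335
1.867288,0.385741061729127,-0.191088622187073,0.416260944302505,-0.225172266736343
15.185937,0.25251481064416,0.521109900282844,0.234711324724698,-0.00833603565170126
10.94039,0.570893000723602,0.357939105251261,0.131618371588045,-0.060455499504536
8.189866,0.792301022718639,0.132023868588158,0.0808401077852935,-0.0437229541902679
17.968303,0.126981017418538,0.496972775665124,0.280061967802146,0.0959842391141916
16.981407,0.165052524531479,0.515712463151915,0.265701371553554,0.053533640763052
-0.165349,0.225088934561696,-0.217203781205948,0.473149179859483,-0.255945398653535
4.557049,0.653458849612767,-0.100407048420148,0.247898707289644,-0.134098369317235
1.248228,0.330664942393601,-0.202678674375936,0.441508191172111,-0.238829516796176
1.600578,0.361318606720208,-0.196492499034023,0.428032441471799,-0.231539942437775
0.196969,0.249603193342524,-0.214986850571533,0.46831989509448,-0.253333044522947
11.076728,0.557909314466734,0.367542533949468,0.135663997431627,-0.0611158476985743
-1.398419,0.153749004848905,-0.21759824692999,0.474008470304505,-0.256410223374515
11.094094,0.556268405329789,0.368743859663629,0.136176196164142,-0.06118846115756
0.334787,0.259375830270129,-0.213878631802464,0.465905789783888,-0.252027157981424
16.217324,0.199263382357625,0.522755248134856,0.25331757280884,0.0246637966986791
-6.079126,0.0176174362666327,-0.139439310953445,0.303749756341659,-0.164310445388214
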