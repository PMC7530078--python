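study_id,author,year,pmid,country,population,dna_source,alleles,outcome,rr,ci_lower,ci_upper
s01,Author01,2005,30262022,USA,caucasian,non_neoplastic,*10;*4,recurrence,1.6006879382287673,0.8968039538439347,2.857036774435259
s02,Author02,2009,15704725,USA,caucasian,non_neoplastic,*10;*4;*41,recurrence,1.398827248912843,0.8572788792981961,2.2824750726425487
s03,Author03,2003,20324395,UK,caucasian,non_neoplastic,*10;*4,recurrence,1.4555271075739715,0.8018945793288187,2.641942239659325
s04,Author04,2005,20425970,UK,caucasian,non_neoplastic,*4;*41,composite,1.297150467262493,0.9394710077920445,1.791007195287237
s05,Author05,2007,25741752,UK,caucasian,non_neoplastic,*10;*4,recurrence,1.363345935054282,0.6946598768926543,2.675715411898276
s06,Author06,2005,11051132,Denmark,caucasian,non_neoplastic,*4;*41,recurrence,1.246033600253125,0.7271964982020289,2.135048417860262
s07,Author07,2015,16066031,Germany,caucasian,non_neoplastic,*10;*4,composite,1.2239478229201373,0.8998936649925973,1.6646947650679007
s08,Author08,2006,11430249,Germany,caucasian,non_neoplastic,*10;*4,recurrence,1.146485355401366,0.5561629910686624,2.3633875163540337
s09,Author09,2017,26133725,UK,caucasian,non_neoplastic,*4,recurrence,0.673131968843869,0.4576144886891343,0.9901492603033095
s10,Author10,2012,25930292,USA,caucasian,non_neoplastic,*4,recurrence,0.7960804011579656,0.5379622514511336,1.1780454918506382
s11,Author11,2018,34644099,Denmark,caucasian,non_neoplastic,*4,recurrence,1.095535985309302,0.6928305605202019,1.7323125790041234
s12,Author12,2017,17655877,Denmark,caucasian,non_neoplastic,*4,bc_mortality,1.3412278001552886,0.7042042843557177,2.5545030779743354
s13,Author13,2019,20047987,South Korea,asian,non_neoplastic,*10,recurrence,4.626663970621633,1.6161960505676807,13.244692368558619
s14,Author14,2003,28249276,China,asian,non_neoplastic,*10,bc_mortality,3.479056019570515,1.689767566711318,7.163015213309315
s15,Author15,2003,18099300,South Korea,asian,non_neoplastic,*10;*4,recurrence,1.90351683449925,1.2016557850557148,3.0153196816291667
s16,Author16,2010,20210952,Japan,asian,non_neoplastic,*10,recurrence,2.1495753663756827,0.7414967481966548,6.231550262313067
s17,Author17,2013,22273048,China,asian,non_neoplastic,*10;*4,recurrence,2.2705024179058904,1.4445934255121589,3.5686035521647224
s18,Author18,2004,14621700,South Korea,asian,non_neoplastic,*10,bc_mortality,1.6413790246213862,0.6804428860383042,3.959369930594576
s19,Author19,2013,12433369,Japan,asian,non_neoplastic,*10,composite,1.7091396330170276,0.9352327080578404,3.1234560767403337
s20,Author20,2016,27474240,Japan,asian,non_neoplastic,*10,composite,6.57462058702042,2.6489225156824556,16.318195646480163
s21,Author21,2020,11462380,Denmark,caucasian,tumour,*4,recurrence,0.5331146039917528,0.2402083574278962,1.1831860641010197
s22,Author22,2016,11929570,UK,caucasian,tumour,*4,recurrence,2.009333248037746,1.0504971333121236,3.8433423315876127
s23,Author23,2013,21163750,USA,caucasian,tumour,*4,bc_mortality,1.5456117843629502,0.821995326903947,2.906240108395137
s24,Author24,2016,13871044,Germany,caucasian,tumour,*4,recurrence,1.9875463076277897,1.0672182650257669,3.701529906695781
s25,Author25,2012,12510052,USA,caucasian,tumour,*10;*4,recurrence,2.3198523402233864,1.0103478408543287,5.326596111581986
s26,Author26,2006,26690772,USA,caucasian,tumour,*4;*41,bc_mortality,0.8419827069984984,0.3984609968113808,1.7791826165111644
s27,Author27,2004,20745797,UK,caucasian,tumour,*4,recurrence,1.1678425692190382,0.6167518876859778,2.2113532097927493
s28,Author28,2012,25608136,Denmark,caucasian,tumour,*4,recurrence,0.8275739711214524,0.4616087529704657,1.4836778403150206
s29,Author29,2010,19230109,USA,caucasian,tumour,*4,recurrence,0.9891591250567743,0.6805285183712242,1.4377586659040678
s30,Author30,2017,13632120,Brazil,mixed,unknown,*10;*4,recurrence,2.2651157829814474,1.4621285085321183,3.5090961433086294
s31,Author31,2003,27317247,USA,mixed,unknown,*10;*4,recurrence,1.071824568890515,0.4241788987182074,2.7083098898809674
s32,Author32,2006,21855739,USA,mixed,unknown,*10;*4,recurrence,1.4166856052279204,0.7300251045775876,2.7492179261715983
s33,Author33,2008,17224011,Brazil,mixed,unknown,*10;*4,recurrence,1.3849804290094603,0.6306733028007284,3.0414650187678967
s34,Author34,2011,28355327,Brazil,mixed,unknown,*10;*4,recurrence,2.0903836457848706,1.023581043262051,4.269035476310734
s35,Author35,2003,14506860,USA,mixed,unknown,*10;*4,recurrence,1.334772253015737,0.8553881244170105,2.082817047097734
s36,Author36,2012,32768223,USA,mixed,unknown,*10;*4,bc_mortality,1.3420898346653647,0.5503482611698464,3.2728460347696537
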