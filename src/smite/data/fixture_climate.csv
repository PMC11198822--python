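date,SST,SSS,pH_sw
2010-06,23.919271405859476,34.24781308405555,8.20214702721122
2010-07,23.467037801087336,34.317117588486994,8.20222590883597
2010-08,24.02071010219318,34.18409202552148,8.17920677391525
2010-09,24.687743022734317,34.04043586385354,8.185991041832933
2010-10,25.566297913106084,33.840866494416645,8.155048920193938
2010-11,27.118814362059084,33.5524753148183,8.141890779672103
2010-12,27.944606631524717,33.428939731436365,8.145024883390999
2011-01,27.773936397009578,33.50943955511085,8.12327167837735
2011-02,27.305551040648893,33.61893745131642,8.128292596535246
2011-03,26.333409093830426,33.758141712454545,8.128871316269796
2011-04,24.767552364931994,34.079356814730545,8.160090284547492
2011-05,23.14029828727969,33.81875318652154,8.204430701226402
2011-06,22.39974404936374,34.17420546442437,8.235881725181152
2011-07,22.523367259112504,34.309270695495194,8.203757436145505
2011-08,22.94711375743924,34.27443828653059,8.190775698358063
2011-09,23.832647104745696,32.36763404796033,8.188555337436085
2011-10,25.45459653614809,32.86375856741664,8.183293732518164
2011-11,27.142836284625997,33.011521668596295,8.158079123305388
2011-12,28.099188912480553,33.17193983754717,8.129709574812146
2012-01,28.698408687514426,33.30132609968918,8.123176944852387
2012-02,28.693128471616927,33.35984401271562,8.120807392248041
2012-03,27.61243464657003,33.63410127316713,8.132006931894978
2012-04,25.991760562071935,33.97951622311345,8.145642661587145
2012-05,24.77736135763822,34.225123219269776,8.169580399974565
2012-06,23.87518635813511,34.39072091987773,8.186091224045388
2012-07,23.85849217719736,34.36451822079225,8.184231156118608
2012-08,23.76877200712494,34.35038675036357,8.182462413022574
2012-09,24.57443564694895,34.11156238107313,8.156390391576565
2012-10,25.717898353114094,33.88359921380732,8.139448004258108
2012-11,26.61306804836043,33.69484316810847,8.14630201514308
2012-12,27.800632496220825,33.500160961603385,8.126621859123784
2013-01,28.4569176531684,33.031105627014504,8.100449074872481
2013-02,27.944937394612793,33.3228984642926,8.128631242888408
2013-03,27.495091531439268,33.542525466483774,8.140067879481856
2013-04,26.424114510050188,33.80898652864417,8.177364607549794
2013-05,25.250451003077817,33.69560365725011,8.185121840310593
2013-06,24.343398821062085,33.51075197725349,8.185501955616425
2013-07,24.229027201478008,33.77748718116529,8.166729069665713
2013-08,24.086402258268247,33.949301729087374,8.18730676626629
2013-09,25.263293485884542,33.797904473481836,8.198536926966684
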