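date,SrCa,d18O,d11B,BCa,LiCa,MgCa,UCa,SrCa_sigma,d18O_sigma,d11B_sigma,BCa_sigma,LiCa_sigma,MgCa_sigma,UCa_sigma
2010-06,9.10110022566433,-4.899230176594085,23.410824911301724,497.98313876587457,6.2941473736073785,4.103464455083347,1.2979539517918592,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2010-07,9.128550805474,-4.781026567347726,23.47558825423733,488.58344230628506,6.361254982581007,3.9481661862516004,1.224077106597217,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2010-08,9.094942896796875,-4.9387513755917,23.220103553150356,489.48192696892863,6.5400574768805875,3.8665169270660487,1.1669616863516898,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2010-09,9.054453998520028,-5.124285781761094,23.17266715027645,484.40430288404133,6.520945653341892,4.114278846951286,1.08853106982769,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2010-10,9.001125716674462,-5.371451587390845,22.812559003849323,458.11537129358965,6.322615558785556,4.267077233551552,1.0738487927450822,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2010-11,8.906887968223014,-5.790870824652057,22.492114285692434,439.12018898446456,5.980142649376655,4.174284404058638,1.2078905429105595,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2010-12,8.85676237746645,-6.005899731447619,22.39856469167971,436.6676198893007,5.87228756373307,4.6035021120739,1.0203734472848662,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-01,8.867122060701519,-5.946617327462177,22.269557661914554,428.8664539397901,5.877470946252114,3.8915717295218575,1.1102019889427979,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-02,8.895553051832612,-5.814008117087323,22.375167424669023,434.24733809433604,5.396860736078025,4.051105053485598,1.0733634971445176,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-03,8.954562068004494,-5.562551738279967,22.515159618536114,448.1389940095949,5.810017552590526,4.202133511682605,1.1523680334083186,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-04,9.049609571448629,-5.131335180307792,22.972932577092518,461.308880675992,6.419762158013576,4.0447043435852486,1.2151559755108838,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-05,9.148383893962123,-4.843702262840717,23.49003834228408,503.40015028365434,6.8250799743274575,3.5367180914851204,1.1940887612057536,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-06,9.193335536203621,-4.5848082154654435,23.85486538123324,482.133503744588,6.537549400143953,3.810371762161209,1.2632006360491366,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-07,9.185831607371872,-4.57553770922105,23.60735980516628,510.15889626856693,7.0700339476136875,4.052395318150525,1.2638912128939184,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-08,9.160110194923439,-4.6781666892733735,23.45217882688022,484.4445177246686,6.607940964829335,3.9554936445312983,1.2464135349408467,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-09,9.106358320741936,-5.387821170094765,23.149910584466085,476.56769189911273,6.4841322409315145,3.995994913114634,1.215372115871716,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-10,9.00790599025581,-5.610696424750088,22.947931737204023,448.9176742407746,6.284406073593366,4.3389605064849865,1.1562619463587005,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-11,8.905429837523203,-5.942213132096719,22.558665401498708,445.77134204344054,6.035293144470795,4.442865105350838,1.160826556753383,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2011-12,8.84737923301243,-6.109297804607986,22.244645736851105,431.40102463257546,5.321198679648862,4.175197558126492,1.1638209652842775,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-01,8.811006592667875,-6.206191864337097,22.133053879330973,430.7367318815733,5.743601228728681,4.4954343449430665,1.0959426577826274,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-02,8.811327101772854,-6.189230380322507,22.12190386439871,420.5193031022322,5.535688963638104,4.889775488334655,1.0125171855468873,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-03,8.8769252169532,-5.877428278490281,22.3645198054099,441.16215419016163,5.5654207002102325,4.120275215075331,1.1176178725790982,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-04,8.975300133882234,-5.4276179434151945,22.701159890258506,482.51464116820085,6.002918002270977,4.241058381627511,1.1426486584724869,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-05,9.04901416559136,-5.094136229477569,23.05505007729616,478.0429681676596,5.837979457122665,3.9610038443193174,1.2122786397836625,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-06,9.1037761880612,-4.850946350422737,23.308418388967464,475.4593155834305,6.378985188003071,3.708891283718648,1.3326375894092077,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-07,9.104789524844122,-4.854348359369512,23.294314644217852,496.38327800894047,6.565974592476598,3.6794360070625465,1.2000143192165853,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-08,9.110235539167517,-4.838425418969323,23.291297421127997,482.16581124839746,6.379755711254607,3.963687266006919,1.213854297406914,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-09,9.0613317562302,-5.080153999439025,22.972917413865318,480.92188751608825,6.274375802951673,4.139065315336666,1.1218373354611713,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-10,8.991923569965975,-5.393265849957124,22.682009448521534,467.83024168786216,6.074122713162196,4.282967674151825,1.1224082721457536,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-11,8.937586769464524,-5.641167315250007,22.6015852517871,446.1002426809876,5.959627971175984,3.9126579068878056,1.0884408098157663,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2012-12,8.865501607479397,-5.954995689535667,22.289611771967483,410.8083025889425,5.924916031481246,4.370069645104305,1.1867268839520542,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-01,8.82566509845268,-6.226023364403132,21.97626321809153,422.8425724400055,5.526561233035334,4.639426469845807,1.0711568502291313,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-02,8.856742300147005,-6.034603641455813,22.270003051566878,443.76781452957937,5.612606996586017,4.70791371668537,1.0457554218776128,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-03,8.884047944041637,-5.876338260966019,22.42996411667694,436.8099649010549,5.894304511975313,4.573055807607076,1.2238612928300188,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-04,8.949056249239955,-5.568778829477116,22.864812642162867,463.26610035408197,6.498370975616694,4.453388737612523,1.0650074494551787,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-05,9.020297624113176,-5.34118623321959,23.06318550334792,483.19395360547554,6.186909198703389,4.38495995480356,1.2373581109466933,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-06,9.075355691561532,-5.1915447067752165,23.16597981661932,471.19572180904913,6.550957668919034,4.2130675991975455,1.2684268366319058,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-07,9.082298048870285,-5.094364445410532,23.064412664403562,494.3753642694156,6.073956738101939,3.792209434498594,1.2301904411965718,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-08,9.090955382923118,-5.016597029965424,23.25159825219728,503.72644572260486,6.789455573712455,3.981653829258165,1.1938017093004731,0.009,0.1,0.09,8.0,0.12,0.1,0.03
2013-09,9.019518085406808,-5.3163903590545045,23.17076240355814,486.1195087881445,6.430169242456828,3.895462713602984,1.1826385106293535,0.009,0.1,0.09,8.0,0.12,0.1,0.03
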