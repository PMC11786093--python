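level,region,name,population_2000,deaths_2000_2010,population_2010,deaths_2010_2020
region,North China,North China,63775078,1800,79983172,-11073
region,Northeast China,Northeast China,48883249,-979,54959830,-1444
region,East China,East China,127914533,8767,146544502,-12277
region,Central China,Central China,160744566,2562,63188415,-7234
region,South China,South China,40192320,-1381,47420822,-295
region,Southwest China,Southwest China,30983255,-609,34097203,-2196
region,Northwest China,Northwest China,24738979,-209,29374686,-3134
province,North China,Beijing,10710832,-308,16545554,-2683
province,North China,Tianjin,6500178,90,9197794,-1072
province,North China,Hebei,24353203,1487,28270942,-4019
province,North China,Shanxi,14618624,388,17064195,-2524
province,North China,Inner Mongolia,7592241,143,8904686,-775
province,Northeast China,Liaoning,21903437,662,24758787,-1320
province,Northeast China,Jilin,11742940,-753,12803860,-261
province,Northeast China,Heilongjiang,15236871,-888,17397183,137
province,East China,Shanghai,7135130,416,11819133,-909
province,East China,Jiangsu,23614032,1677,25577172,-2105
province,East China,Zhejiang,12888906,696,16324765,-534
province,East China,Anhui,18024866,1624,18470001,-2460
province,East China,Fujian,11572315,384,13773340,16
province,East China,Jiangxi,9080980,785,10589480,-376
province,East China,Shandong,30885628,2894,33993997,-5362
province,East China,Taiwan,14712678,290,15996613,-693
province,Central China,Henan,27355634,1868,28866333,-4267
province,Central China,Hubei,118017596,653,17023172,-1821
province,Central China,Hunan,15371336,41,17298910,-1146
province,South China,Guangdong,27684031,-766,33402262,-70
province,South China,Guangxi,6792098,-236,7028549,-25
province,South China,Hainan,1822040,81,2367704,-73
province,South China,Hong Kong,3740298,-463,4418702,-121
province,South China,Macao,153853,3,203606,-5
province,Southwest China,Chongqing,6289639,-382,6419435,-259
province,Southwest China,Sichuan,12463490,-612,13691385,-555
province,Southwest China,Guizhou,5535802,-142,6184507,-603
province,Southwest China,Yunnan,6504222,518,7569020,-775
province,Southwest China,Tibet,190103,9,232857,-4
province,Northwest China,Shaanxi,9573219,-50,10732585,-1579
province,Northwest China,Gansu,5646554,-131,6221693,-719
province,Northwest China,Qinghai,1311369,176,1642268,-254
province,Northwest China,Ningxia,1931743,20,2499877,-303
province,Northwest China,Xinjiang,6276094,-223,8278262,-279
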