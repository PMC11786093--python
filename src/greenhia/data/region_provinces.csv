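province,region
Beijing,North China
Tianjin,North China
Hebei,North China
Shanxi,North China
Inner Mongolia,North China
Liaoning,Northeast China
Jilin,Northeast China
Heilongjiang,Northeast China
Shanghai,East China
Jiangsu,East China
Zhejiang,East China
Anhui,East China
Fujian,East China
Jiangxi,East China
Shandong,East China
Taiwan,East China
Henan,Central China
Hubei,Central China
Hunan,Central China
Guangdong,South China
Guangxi,South China
Hainan,South China
Hong Kong,South China
Macao,South China
Chongqing,Southwest China
Sichuan,Southwest China
Guizhou,Southwest China
Yunnan,Southwest China
Tibet,Southwest China
Shaanxi,Northwest China
Gansu,Northwest China
Qinghai,Northwest China
Ningxia,Northwest China
Xinjiang,Northwest China
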