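province_name,primacy_ratio,primate_city,secondary_city
Sichuan,5.11,Chengdu,Mianyang
Hubei,3.96,Wuhan,Yichang
Yunnan,3.78,Kunming,Qujing
Xinjiang,3.58,Urumqi,Changji Hui Autonomous Prefecture
Heilongjiang,3.22,Harbin,Daqing
Shaanxi,3.07,Xi'an,Baoji
Tibet,2.72,Lhasa,Ngari Prefecture
Qinghai,2.61,Xining,Haixi Mongolian and Tibetan Autonomous Prefecture
Jilin,2.59,Changchun,Jilin
Hunan,2.45,Changsha,Hengyang
Hainan,2.34,Haikou,Sanya
Ningxia,2.19,Yinchuan,Shizuishan
Anhui,2.19,Hefei,Fuyang
Henan,2.11,Zhengzhou,Nanyang
Zhejiang,2.05,Hangzhou,Wenzhou
Guizhou,1.98,Guiyang,Zunyi
Gansu,1.96,Lanzhou,Qingyang
Shanxi,1.82,Taiyuan,Datong
Guangxi,1.78,Nanning,Guilin
Guangdong,1.75,Guangzhou,Shenzhen
Jiangsu,1.39,Nanjing,Xuzhou
Liaoning,1.36,Shenyang,Dalian
Hebei,1.36,Shijiazhuang,Baoding
Fujian,1.26,Fuzhou,Quanzhou
Jiangxi,1.24,Nanchang,Ganzhou
Shandong,1.19,Qingdao,Jinan
Inner Mongolia,1.16,Hohhot,Baotou
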