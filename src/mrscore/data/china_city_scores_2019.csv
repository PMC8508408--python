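city_level,province_name,city_name,score,national_rank,provincial_rank
First-tier city,Beijing,Beijing,92.89,1,1
First-tier city,Shanghai,Shanghai,67.54,2,1
First-tier city,Guangdong,Guangzhou,65.20,3,1
New first-tier city,Chongqing,Chongqing,65.05,4,1
New first-tier city,Sichuan,Chengdu,63.03,5,1
New first-tier city,Liaoning,Shenyang,50.19,6,1
New first-tier city,Zhejiang,Hangzhou,48.55,7,1
New first-tier city,Hubei,Wuhan,48.05,8,1
New first-tier city,Henan,Zhengzhou,44.18,9,1
New first-tier city,Tianjin,Tianjin,43.38,10,1
Second-tier city,Heilongjiang,Harbin,40.88,11,1
New first-tier city,Shaanxi,Xi'an,40.30,12,1
Second-tier city,Jilin,Changchun,38.96,13,1
New first-tier city,Shandong,Qingdao,38.10,14,1
First-tier city,Guangdong,Shenzhen,37.30,15,2
Second-tier city,Hebei,Shijiazhuang,37.18,16,1
Second-tier city,Liaoning,Dalian,36.86,17,2
New first-tier city,Hunan,Changsha,35.88,18,1
Second-tier city,Yunnan,Kunming,33.77,19,1
New first-tier city,Jiangsu,Nanjing,32.06,20,1
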