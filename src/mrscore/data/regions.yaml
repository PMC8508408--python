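# Province -> region memberships used for aggregate equity summaries.
# sectors: National Bureau of Statistics 4-part division of the economy.
# zones: State Council 8 economic zones (mainland provinces only).
# Editable: provinces may be remapped, but every province must belong to
# exactly one sector, and every mainland province to exactly one zone.
sectors:
  NES: [Liaoning, Jilin, Heilongjiang]
  ES: [Beijing, Tianjin, Hebei, Shanghai, Jiangsu, Zhejiang, Fujian, Shandong,
       Guangdong, Hainan, Hong Kong, Macao]
  CS: [Shanxi, Anhui, Jiangxi, Henan, Hubei, Hunan]
  WS: [Inner Mongolia, Guangxi, Chongqing, Sichuan, Guizhou, Yunnan, Tibet,
       Shaanxi, Gansu, Qinghai, Ningxia, Xinjiang]
zones:
  NEEZ: [Liaoning, Jilin, Heilongjiang]
  NCEZ: [Beijing, Tianjin, Hebei, Shandong]
  ECEZ: [Shanghai, Jiangsu, Zhejiang]
  SCEZ: [Fujian, Guangdong, Hainan]
  MRYLREZ: [Shaanxi, Shanxi, Henan, Inner Mongolia]
  MRYZREZ: [Hubei, Hunan, Jiangxi, Anhui]
  SWEZ: [Yunnan, Guizhou, Sichuan, Chongqing, Guangxi]
  NWEZ: [Gansu, Qinghai, Ningxia, Tibet, Xinjiang]
# Units scored under a separate hospital-rating system; accepted at ingest
# but excluded from scoring and equity summaries.
excluded_provinces: [Hong Kong, Macao]
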