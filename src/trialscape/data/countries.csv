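code,name,population_2012,income_group,region,continent
US,United States,313914040,high,North America,North America
CA,Canada,34754312,high,North America,North America
GB,United Kingdom,63700215,high,Western Europe,Europe
DE,Germany,80425823,high,Western Europe,Europe
FR,France,65676758,high,Western Europe,Europe
IT,Italy,59539717,high,Western Europe,Europe
ES,Spain,46773055,high,Western Europe,Europe
NL,Netherlands,16754962,high,Western Europe,Europe
SE,Sweden,9519374,high,Western Europe,Europe
DK,Denmark,5591572,high,Western Europe,Europe
NO,Norway,5018573,high,Western Europe,Europe
FI,Finland,5413971,high,Western Europe,Europe
CH,Switzerland,7996861,high,Western Europe,Europe
AT,Austria,8429991,high,Western Europe,Europe
BE,Belgium,11128246,high,Western Europe,Europe
AU,Australia,22728254,high,Oceania,Oceania
NZ,New Zealand,4408100,high,Oceania,Oceania
JP,Japan,127561489,high,Asia,Asia
KR,South Korea,50004441,high,Asia,Asia
IL,Israel,7910500,high,Asia,Asia
BR,Brazil,198656019,upper_middle,South America,South America
AR,Argentina,41086927,upper_middle,South America,South America
MX,Mexico,120847477,upper_middle,North America,North America
RU,Russia,143201676,upper_middle,Eastern Europe,Europe
TR,Turkey,73997128,upper_middle,Asia,Asia
ZA,South Africa,52274945,upper_middle,Africa,Africa
CN,China,1350695000,upper_middle,Asia,Asia
RO,Romania,20076727,upper_middle,Eastern Europe,Europe
BG,Bulgaria,7305888,upper_middle,Eastern Europe,Europe
RS,Serbia,7199077,upper_middle,Eastern Europe,Europe
HU,Hungary,9920362,upper_middle,Eastern Europe,Europe
IN,India,1236686732,lower_middle,Asia,Asia
UA,Ukraine,45593300,lower_middle,Eastern Europe,Europe
EG,Egypt,80721874,lower_middle,Africa,Africa
NG,Nigeria,168833776,lower_middle,Africa,Africa
PH,Philippines,96706764,lower_middle,Asia,Asia
ID,Indonesia,246864191,lower_middle,Asia,Asia
ET,Ethiopia,91728849,low,Africa,Africa
TZ,Tanzania,47783107,low,Africa,Africa
UG,Uganda,36345860,low,Africa,Africa
MW,Malawi,15906483,low,Africa,Africa
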