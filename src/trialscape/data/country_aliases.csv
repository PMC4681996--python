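alias,code
USA,US
United States of America,US
U.S.A.,US
UK,GB
Great Britain,GB
United Kingdom of Great Britain and Northern Ireland,GB
Korea,KR
"Korea, Republic of",KR
Republic of Korea,KR
Russian Federation,RU
"Tanzania, United Republic of",TZ
United Republic of Tanzania,TZ
Holland,NL
The Netherlands,NL
Czech Republic,CZ
Viet Nam,VN
Deutschland,DE
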