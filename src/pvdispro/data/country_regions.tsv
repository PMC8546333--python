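code	name	region
US	United States	North America
CA	Canada	North America
MX	Mexico	North America
GT	Guatemala	North America
BZ	Belize	North America
SV	El Salvador	North America
HN	Honduras	North America
NI	Nicaragua	North America
CR	Costa Rica	North America
PA	Panama	North America
CU	Cuba	North America
DO	Dominican Republic	North America
HT	Haiti	North America
JM	Jamaica	North America
TT	Trinidad and Tobago	North America
BS	Bahamas	North America
BB	Barbados	North America
PR	Puerto Rico	North America
GL	Greenland	North America
BM	Bermuda	North America
LC	Saint Lucia	North America
GD	Grenada	North America
AG	Antigua and Barbuda	North America
DM	Dominica	North America
KN	Saint Kitts and Nevis	North America
VC	Saint Vincent and the Grenadines	North America
AW	Aruba	North America
CW	Curacao	North America
KY	Cayman Islands	North America
MQ	Martinique	North America
GP	Guadeloupe	North America
VI	Virgin Islands	North America
BR	Brazil	South America
AR	Argentina	South America
CL	Chile	South America
CO	Colombia	South America
PE	Peru	South America
VE	Venezuela	South America
EC	Ecuador	South America
BO	Bolivia	South America
PY	Paraguay	South America
UY	Uruguay	South America
GY	Guyana	South America
SR	Suriname	South America
GF	French Guiana	South America
FK	Falkland Islands	South America
GB	United Kingdom	Europe
DE	Germany	Europe
FR	France	Europe
IT	Italy	Europe
ES	Spain	Europe
PT	Portugal	Europe
NL	Netherlands	Europe
BE	Belgium	Europe
LU	Luxembourg	Europe
IE	Ireland	Europe
DK	Denmark	Europe
SE	Sweden	Europe
NO	Norway	Europe
FI	Finland	Europe
IS	Iceland	Europe
CH	Switzerland	Europe
AT	Austria	Europe
PL	Poland	Europe
CZ	Czech Republic	Europe
SK	Slovakia	Europe
HU	Hungary	Europe
RO	Romania	Europe
BG	Bulgaria	Europe
GR	Greece	Europe
HR	Croatia	Europe
SI	Slovenia	Europe
RS	Serbia	Europe
BA	Bosnia and Herzegovina	Europe
ME	Montenegro	Europe
MK	North Macedonia	Europe
AL	Albania	Europe
EE	Estonia	Europe
LV	Latvia	Europe
LT	Lithuania	Europe
BY	Belarus	Europe
UA	Ukraine	Europe
MD	Moldova	Europe
RU	Russia	Europe
MT	Malta	Europe
CY	Cyprus	Europe
AD	Andorra	Europe
MC	Monaco	Europe
SM	San Marino	Europe
LI	Liechtenstein	Europe
VA	Vatican City	Europe
GI	Gibraltar	Europe
JE	Jersey	Europe
GG	Guernsey	Europe
IM	Isle of Man	Europe
FO	Faroe Islands	Europe
XK	Kosovo	Europe
CN	China	Asia
JP	Japan	Asia
KR	South Korea	Asia
KP	North Korea	Asia
IN	India	Asia
PK	Pakistan	Asia
BD	Bangladesh	Asia
LK	Sri Lanka	Asia
NP	Nepal	Asia
BT	Bhutan	Asia
MV	Maldives	Asia
AF	Afghanistan	Asia
IR	Iran	Asia
IQ	Iraq	Asia
SY	Syria	Asia
LB	Lebanon	Asia
JO	Jordan	Asia
IL	Israel	Asia
PS	Palestine	Asia
SA	Saudi Arabia	Asia
YE	Yemen	Asia
OM	Oman	Asia
AE	United Arab Emirates	Asia
QA	Qatar	Asia
BH	Bahrain	Asia
KW	Kuwait	Asia
TR	Turkey	Asia
GE	Georgia	Asia
AM	Armenia	Asia
AZ	Azerbaijan	Asia
KZ	Kazakhstan	Asia
UZ	Uzbekistan	Asia
TM	Turkmenistan	Asia
KG	Kyrgyzstan	Asia
TJ	Tajikistan	Asia
MN	Mongolia	Asia
TH	Thailand	Asia
VN	Vietnam	Asia
LA	Laos	Asia
KH	Cambodia	Asia
MM	Myanmar	Asia
MY	Malaysia	Asia
SG	Singapore	Asia
ID	Indonesia	Asia
PH	Philippines	Asia
BN	Brunei	Asia
TL	Timor-Leste	Asia
TW	Taiwan	Asia
HK	Hong Kong	Asia
MO	Macau	Asia
AU	Australia	Oceania
NZ	New Zealand	Oceania
PG	Papua New Guinea	Oceania
FJ	Fiji	Oceania
SB	Solomon Islands	Oceania
VU	Vanuatu	Oceania
WS	Samoa	Oceania
TO	Tonga	Oceania
KI	Kiribati	Oceania
FM	Micronesia	Oceania
MH	Marshall Islands	Oceania
PW	Palau	Oceania
NR	Nauru	Oceania
TV	Tuvalu	Oceania
NC	New Caledonia	Oceania
PF	French Polynesia	Oceania
GU	Guam	Oceania
ZA	South Africa	Africa
EG	Egypt	Africa
NG	Nigeria	Africa
KE	Kenya	Africa
ET	Ethiopia	Africa
TZ	Tanzania	Africa
UG	Uganda	Africa
GH	Ghana	Africa
DZ	Algeria	Africa
MA	Morocco	Africa
TN	Tunisia	Africa
LY	Libya	Africa
SD	Sudan	Africa
SS	South Sudan	Africa
SN	Senegal	Africa
ML	Mali	Africa
BF	Burkina Faso	Africa
NE	Niger	Africa
TD	Chad	Africa
CM	Cameroon	Africa
CI	Ivory Coast	Africa
GN	Guinea	Africa
BJ	Benin	Africa
TG	Togo	Africa
LR	Liberia	Africa
SL	Sierra Leone	Africa
GM	Gambia	Africa
GW	Guinea-Bissau	Africa
MR	Mauritania	Africa
CV	Cabo Verde	Africa
CD	Democratic Republic of the Congo	Africa
CG	Congo	Africa
GA	Gabon	Africa
GQ	Equatorial Guinea	Africa
CF	Central African Republic	Africa
AO	Angola	Africa
ZM	Zambia	Africa
ZW	Zimbabwe	Africa
MW	Malawi	Africa
MZ	Mozambique	Africa
BW	Botswana	Africa
NA	Namibia	Africa
SZ	Eswatini	Africa
LS	Lesotho	Africa
MG	Madagascar	Africa
MU	Mauritius	Africa
SC	Seychelles	Africa
KM	Comoros	Africa
DJ	Djibouti	Africa
SO	Somalia	Africa
ER	Eritrea	Africa
RW	Rwanda	Africa
BI	Burundi	Africa
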