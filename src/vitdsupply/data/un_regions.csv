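country,region
Afghanistan,Asia
Albania,Europe
Algeria,Africa
Angola,Africa
Antigua and Barbuda,Americas
Argentina,Americas
Armenia,Asia
Australia,Oceania
Austria,Europe
Azerbaijan,Asia
Bahamas,Americas
Bangladesh,Asia
Barbados,Americas
Belarus,Europe
Belgium,Europe
Belize,Americas
Benin,Africa
Bermuda,Americas
Bolivia (Plurinational State of),Americas
Bosnia and Herzegovina,Europe
Botswana,Africa
Brazil,Americas
Brunei Darussalam,Asia
Bulgaria,Europe
Burkina Faso,Africa
Cabo Verde,Africa
Cambodia,Asia
Cameroon,Africa
Canada,Americas
Central African Republic,Africa
Chad,Africa
Chile,Americas
China,Asia
"China, Hong Kong SAR",Asia
"China, Macao SAR",Asia
"China, Taiwan Province of",Asia
"China, mainland",Asia
Colombia,Americas
Congo,Africa
Costa Rica,Americas
Cote d'Ivoire,Africa
Croatia,Europe
Cuba,Americas
Cyprus,Asia
Czechia,Europe
DPR of Korea,Asia
Denmark,Europe
Djibouti,Africa
Dominica,Americas
Dominican Republic,Americas
Ecuador,Americas
Egypt,Africa
El Salvador,Americas
Estonia,Europe
Eswatini,Africa
Ethiopia,Africa
Fiji,Oceania
Finland,Europe
France,Europe
French Polynesia,Oceania
Gabon,Africa
Gambia,Africa
Georgia,Asia
Germany,Europe
Ghana,Africa
Greece,Europe
Grenada,Americas
Guatemala,Americas
Guinea,Africa
Guinea-Bissau,Africa
Guyana,Americas
Haiti,Americas
Honduras,Americas
Hungary,Europe
Iceland,Europe
India,Asia
Indonesia,Asia
Iran (Islamic Republic of),Asia
Iraq,Asia
Ireland,Europe
Israel,Asia
Italy,Europe
Jamaica,Americas
Japan,Asia
Jordan,Asia
Kazakhstan,Asia
Kenya,Africa
Kiribati,Oceania
Kuwait,Asia
Kyrgyzstan,Asia
Lao PDR,Asia
Latvia,Europe
Lebanon,Asia
Lesotho,Africa
Liberia,Africa
Lithuania,Europe
Luxembourg,Europe
Madagascar,Africa
Malawi,Africa
Malaysia,Asia
Maldives,Asia
Mali,Africa
Malta,Europe
Mauritania,Africa
Mauritius,Africa
Mexico,Americas
Mongolia,Asia
Montenegro,Europe
Morocco,Africa
Mozambique,Africa
Myanmar,Asia
Namibia,Africa
Nepal,Asia
Netherlands,Europe
Netherlands Antilles (former),Americas
New Caledonia,Oceania
New Zealand,Oceania
Nicaragua,Americas
Niger,Africa
Nigeria,Africa
North Macedonia,Europe
Norway,Europe
Oman,Asia
Pakistan,Asia
Panama,Americas
Paraguay,Americas
Peru,Americas
Philippines,Asia
Poland,Europe
Portugal,Europe
Republic of Korea,Asia
Republic of Moldova,Europe
Romania,Europe
Russian Federation,Europe
Rwanda,Africa
Saint Kitts and Nevis,Americas
Saint Lucia,Americas
Saint Vincent and the Grenadines,Americas
Samoa,Oceania
Sao Tome and Principe,Africa
Saudi Arabia,Asia
Senegal,Africa
Serbia,Europe
Serbia and Montenegro,Europe
Sierra Leone,Africa
Slovakia,Europe
Slovenia,Europe
Solomon Islands,Oceania
South Africa,Africa
Spain,Europe
Sri Lanka,Asia
Sudan,Africa
Sudan (former),Africa
Suriname,Americas
Sweden,Europe
Switzerland,Europe
Tajikistan,Asia
Thailand,Asia
Timor-Leste,Asia
Togo,Africa
Trinidad and Tobago,Americas
Tunisia,Africa
Turkey,Asia
Turkmenistan,Asia
Uganda,Africa
Ukraine,Europe
United Arab Emirates,Asia
United Kingdom,Europe
United Republic of Tanzania,Africa
United States of America,Americas
Uruguay,Americas
Uzbekistan,Asia
Vanuatu,Oceania
Venezuela (Bolivarian Republic of),Americas
Viet Nam,Asia
Yemen,Asia
Zambia,Africa
Zimbabwe,Africa
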