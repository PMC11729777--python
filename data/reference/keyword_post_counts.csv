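keyword,category,posts
weed,cannabinoid,23031
blunt,cannabinoid,13319
joint,cannabinoid,2549
dank,cannabinoid,1830
marijuana,cannabinoid,1619
420,cannabinoid,44
mary jane,cannabinoid,38
molly,stimulant_hallucinogen,9984
cocaine,stimulant_hallucinogen,5096
coke,stimulant_hallucinogen,4007
powder,stimulant_hallucinogen,2865
cigarette,stimulant_hallucinogen,1910
crack,stimulant_hallucinogen,54
mushroom,stimulant_hallucinogen,26
ketamine,stimulant_hallucinogen,7
dope,opioid,11958
heroin,opioid,811
oxy,opioid,189
liquor,other,4524
wine,other,2795
xan,other,1460
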