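species	subgroup	enzyme	fragments
Kluyveromyces marxianus	I	HaeIII	655,80
Kluyveromyces marxianus	I	HinfI	240,185,120,80
Kluyveromyces marxianus	II	HaeIII	655,80
Kluyveromyces marxianus	II	HinfI	240,185,140,80
Saccharomyces cerevisiae		HaeIII	320,230,180,150
Saccharomyces cerevisiae		HinfI	365,155
Pichia fermentans		HaeIII	340,80
Pichia fermentans		HinfI	250,200
Kazachstania unispora		HaeIII	550,150
Kazachstania unispora		HinfI	370
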