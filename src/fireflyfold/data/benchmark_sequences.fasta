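>HP1
hphhpphhhhphhhpphhpphphhhphphhpphhppphpppppppphh
>HP2
hhhhphhphhhhhpphpphhpphpppppphpphppphpphhpphhhph
>HP3
phphhphhhhhhpphphpphphhphphppphpphhpphhpphphpphp
>HP4
phphhpphphhhpphhphhppphhhhhpphphhphphpppphpphphp
>HP5
pphppphphhhhpphhhhphhphhhpphphphpphpppppphhphhph
>HP6
hhhppphhphphhphhphhphppppppphphpphppphpphhhhhhph
>HP7
phpppphphhhphphhhhphhphhppphphppphhhpphhpphhppph
>HP8
phhphhhphhhhpphhhpppppphphhpphhphppphhphphphhppp
>HP9
phphpppphphphpphphhhhhhpphhhphpphphhpphphhhpppph
>HP10
phhpppppphhppphhhphpphphhpphpphpphhpphhhhhhhpphh
>MJ1
frtrplnhdfynykiwepfkpadfpkawdrmldhvwdsmaswghqhcs
>MJ2
cdlppftyrhhgndfwknyemikhwdlwrdmfrafwsdpvkasphqas
>MJ3
frtpwvshqfyayklmehfkwgdfcrnmdkwidslpdrwnpaphdhas
>MJ4
kdkihfrmnygypawdaqsvkdltcprdwhfphmrdpshnwelaffws
>MJ5
endvtmdmdpspclfrihnlprahsfdrfgwhqfdkyhykwkwawaps
>MJ6
ehdaqldfdwsrwtwhgrnsyhapamyrwpvhdmdkpnpkfkifflcs
>4RXN
mkkytctvcgyiydpedgdpddgvnpgtdfkdipddwvcplcgvgkdefeevee
>1ENH
rprtafsseqlarlkrefnenrylterrrqqlsselglneaqikiwfqnkraki
>4PTI
rpdfcleppytgpckariiryfynakaglcqtfvyggcrakrnnfksaedcmrtcgga
>2IGD
mtpavttyklvingktlkgetttkavdaetaekafkqyandngvdgvwtyddatktftvte
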