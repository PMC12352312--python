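# Fixture genus reference list (demo scale; supply a full export for real use)
Acacia
Ahnfeltia
Atriplex
Banksia
Boronia
Brachyscome
Callistemon
Calytrix
Correa
Daviesia
Dianella
Dodonaea
Drosera
Epacris
Eremophila
Eucalyptus
Gahnia
Goodenia
Grevillea
Hakea
Hibbertia
Hovea
Juncus
Kennedia
Leptospermum
Leucopogon
Lomandra
Melaleuca
Odontites
Olearia
Photinia
Pimelea
Plantago
Pomaderris
Prostanthera
Pultenaea
Ranunculus
Rytidosperma
Senecio
Solanum
Stylidium
Swainsona
Telopea
Themeda
Thysanotus
Veronica
Wahlenbergia
Westringia
Xanthorrhoea
Zieria
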