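# Fixture taxon-authority reference list (demo scale)
(DC.) Benth.
(Labill.) R.Br.
(L.) Aiton
(Sm.) Druce
A.Cunn.
A.S.George
Benth.
Black
Bonpl.
Cav.
DC.
Desf.
Druce
F.Muell.
G.Forst.
Gaudich.
Gomont
H.Nordensk.
Hook.
Hook.f.
Labill.
Lindl.
L.
Maiden
Miq.
R.Br.
Rudge
Schauer
Schltdl.
Sieber ex Spreng.
Sm.
Spreng.
Turcz.
Vent.
Willd.
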