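# Fixture family reference list (demo scale; supply a full export for real use)
Acanthaceae
Amaranthaceae
Apiaceae
Apocynaceae
Asparagaceae
Asteraceae
Boraginaceae
Brassicaceae
Campanulaceae
Caryophyllaceae
Casuarinaceae
Convolvulaceae
Cyperaceae
Dilleniaceae
Ericaceae
Euphorbiaceae
Fabaceae
Geraniaceae
Gigartinaceae
Goodeniaceae
Haloragaceae
Juncaceae
Lamiaceae
Lauraceae
Liliaceae
Malvaceae
Myrtaceae
Orchidaceae
Orobanchaceae
Phyllanthaceae
Pittosporaceae
Plantaginaceae
Poaceae
Polygonaceae
Proteaceae
Ranunculaceae
Rhamnaceae
Rosaceae
Rubiaceae
Rutaceae
Salicaceae
Sapindaceae
Scrophulariaceae
Solanaceae
Thymelaeaceae
Urticaceae
Violaceae
Zygophyllaceae
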