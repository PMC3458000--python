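# Metazoan phylum names (NCBI taxonomy hierarchy), in conventional report
# order. Used to pull the phylum label out of a taxonomy path and to order
# rows of per-phylum mismatch tables.
Bilateria
Platyhelminthes
Chaetognatha
Chordata
Echinodermata
Hemichordata
Xenoturbellida
Annelida
Echiura
Brachiopoda
Bryozoa
Entoprocta
Mollusca
Myzostomida
Nemertea
Arthropoda
Onychophora
Tardigrada
Priapulida
Sipuncula
Acanthocephala
Cycliophora
Gastrotricha
Kinorhyncha
Loricifera
Micrognathozoa
Nematoda
Nematomorpha
Rotifera
Cnidaria
Ctenophora
Mesozoa
Placozoa
Porifera
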