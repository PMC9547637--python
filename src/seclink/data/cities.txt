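Aachen
Augsburg
Bamberg
Bayreuth
Berlin
Bielefeld
Bochum
Bonn
Bottrop
Braunschweig
Bremen
Bremerhaven
Chemnitz
Coburg
Cottbus
Darmstadt
Dessau
Dortmund
Dresden
Duisburg
Duesseldorf
Eisenach
Emden
Erfurt
Erlangen
Essen
Flensburg
Frankfurt am Main
Frankfurt an der Oder
Freiburg
Fulda
Fuerth
Gelsenkirchen
Gera
Giessen
Goerlitz
Goettingen
Gotha
Greifswald
Guetersloh
Hagen
Halle
Hamburg
Hameln
Hamm
Hanau
Hannover
Heidelberg
Heilbronn
Herne
Hildesheim
Ingolstadt
Jena
Kaiserslautern
Karlsruhe
Kassel
Kempten
Kiel
Koblenz
Koeln
Konstanz
Krefeld
Landshut
Leipzig
Leverkusen
Luebeck
Ludwigsburg
Ludwigshafen
Lueneburg
Magdeburg
Mainz
Mannheim
Marburg
Minden
Moenchengladbach
Muelheim
Muenchen
Muenster
Neubrandenburg
Neumuenster
Neuss
Nuernberg
Oberhausen
Offenbach
Oldenburg
Osnabrueck
Paderborn
Passau
Pforzheim
Plauen
Potsdam
Ravensburg
Recklinghausen
Regensburg
Remscheid
Reutlingen
Rosenheim
Rostock
Saarbruecken
Salzgitter
Schwerin
Siegen
Solingen
Speyer
Stralsund
Stuttgart
Trier
Tuebingen
Ulm
Villingen
Weimar
Wiesbaden
Wilhelmshaven
Wismar
Witten
Wolfsburg
Worms
Wuppertal
Wuerzburg
Zwickau
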