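Ackermann
Adler
Albrecht
Arnold
Bachmann
Baier
Barth
Bauer
Baumann
Baumgartner
Becker
Behrens
Berger
Bergmann
Bertram
Beyer
Biermann
Binder
Bischoff
Blum
Bode
Boehm
Borchert
Brandt
Braun
Brenner
Brinkmann
Bruckner
Brunner
Buchholz
Burger
Busch
Conrad
Cramer
Dietrich
Dittrich
Doering
Dorn
Drescher
Ebert
Eckert
Ehlers
Eichhorn
Engel
Engelhardt
Erdmann
Ernst
Esser
Falk
Fiedler
Fink
Fischer
Franke
Freitag
Frenzel
Freund
Friedrich
Fritsche
Fuchs
Geiger
Geisler
Gerber
Gerlach
Giese
Glaser
Goebel
Graf
Greiner
Grimm
Gross
Gruber
Gruenewald
Haas
Haase
Hagen
Hahn
Hamann
Hansen
Hartmann
Hauser
Heck
Heider
Heilmann
Hein
Heinrich
Heinze
Held
Heller
Henkel
Hennig
Hense
Herbst
Hermann
Herrmann
Hertel
Herzog
Hess
Hesse
Heuer
Hildebrandt
Hiller
Hinz
Hirsch
Hoffmann
Hofmann
Holz
Hoppe
Horn
Huber
Hummel
Jacobi
Jaeger
Jahn
Janssen
Jung
Jungnickel
Kaiser
Kaminski
Kastner
Keller
Kellner
Kern
Kiefer
Kirchner
Klein
Kluge
Knauer
Koch
Koehler
Koenig
Kohl
Kolb
Konrad
Kraft
Kramer
Kraus
Krause
Krebs
Kremer
Krieger
Krueger
Kuehn
Kuhlmann
Kunze
Kurz
Lachmann
Lang
Lange
Langer
Lehmann
Leinweber
Lenz
Lindemann
Lindner
Loewe
Lorenz
Ludwig
Lutz
Maier
Marquardt
Martin
Marx
Maurer
May
Mayer
Meier
Meissner
Menzel
Merkel
Mertens
Metzger
Meyer
Michel
Moeller
Mohr
Moser
Mueller
Naumann
Neubauer
Neumann
Noack
Nowak
Obermeier
Oswald
Ott
Otto
Paulsen
Peters
Petersen
Pfeiffer
Pohl
Popp
Preuss
Rabe
Radtke
Rau
Reichert
Reimann
Reinhardt
Reuter
Richter
Riedel
Ritter
Roeder
Rohde
Rose
Roth
Rudolph
Runge
Sauer
Schaefer
Scharf
Schenk
Scherer
Schilling
Schindler
Schlegel
Schmid
Schmidt
Schmitt
Schmitz
Schneider
Scholz
Schreiber
Schroeder
Schubert
Schulte
Schultz
Schulz
Schumacher
Schuster
Schwab
Schwarz
Seidel
Seifert
Siebert
Simon
Sommer
Sperling
Stahl
Stark
Steffen
Stein
Steiner
Stephan
Stoll
Strauss
Thiel
Thiele
Ullrich
Ulrich
Vogel
Vogt
Voigt
Volk
Wagner
Walter
Weber
Wegener
Weidner
Weiss
Wendt
Wenzel
Werner
Westermann
Wieland
Wilke
Wimmer
Winkler
Winter
Wirth
Witt
Wolf
Wolff
Wulf
Zander
Ziegler
Zimmermann
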