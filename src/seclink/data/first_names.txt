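Alexander
Alina
Amelie
Andrea
Andreas
Angelika
Anja
Anke
Anna
Annalena
Anne
Annette
Anton
Astrid
Barbara
Beate
Benedikt
Benjamin
Bernd
Bernhard
Bettina
Birgit
Bjoern
Brigitte
Carina
Carla
Carolin
Charlotte
Christian
Christiane
Christina
Christoph
Clara
Claudia
Constantin
Cornelia
Dagmar
Daniel
Daniela
David
Dennis
Diana
Dieter
Dirk
Dominik
Dorothea
Edith
Elena
Elias
Elisabeth
Elke
Emil
Emilia
Emma
Erik
Erika
Ernst
Esther
Eva
Fabian
Felix
Ferdinand
Finn
Florian
Frank
Franziska
Frederik
Friedrich
Gabriele
Georg
Gerhard
Gisela
Greta
Gudrun
Gunther
Hanna
Hannes
Hans
Harald
Hedwig
Heike
Heinrich
Heinz
Helena
Helga
Helmut
Henrik
Henriette
Herbert
Hermann
Hildegard
Holger
Hubert
Ida
Ines
Inge
Ingrid
Irene
Iris
Isabel
Jakob
Jan
Jana
Janina
Jens
Joachim
Johann
Johanna
Johannes
Jonas
Jonathan
Josef
Julia
Julian
Juliane
Jutta
Kai
Karin
Karl
Karla
Karoline
Katharina
Kathrin
Katja
Kerstin
Klara
Klaus
Konrad
Konstanze
Kurt
Lara
Laura
Lea
Lena
Leon
Leonie
Lieselotte
Linda
Lisa
Lothar
Louisa
Ludwig
Luise
Lukas
Magdalena
Manfred
Manuela
Marcel
Margarete
Maria
Marie
Marion
Markus
Marlene
Martha
Martin
Martina
Mathilde
Matthias
Maximilian
Melanie
Michael
Michaela
Miriam
Monika
Moritz
Nadine
Natalie
Nele
Nicole
Niklas
Nina
Norbert
Ole
Oliver
Olivia
Oskar
Otto
Pascal
Paul
Paula
Peter
Petra
Philipp
Pia
Rainer
Ralf
Rebecca
Regina
Reinhard
Renate
Richard
Robert
Roland
Rolf
Rosemarie
Rudolf
Ruth
Sabine
Samuel
Sandra
Sarah
Sebastian
Silke
Simon
Simone
Sofia
Sonja
Stefan
Stefanie
Susanne
Sven
Tanja
Theodor
Theresa
Thomas
Thorsten
Tim
Tobias
Ulrich
Ulrike
Ursula
Uta
Uwe
Valentin
Vanessa
Vera
Verena
Viktoria
Vincent
Walter
Werner
Wilhelm
Wolfgang
Yvonne
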