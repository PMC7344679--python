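name,formula,compound_class,intrinsic_charge
catechin,C15H14O6,flavanol,0
epicatechin gallate,C22H18O10,flavanol,0
procyanidin B1,C30H26O12,flavanol,0
quercetin,C15H10O7,flavonol,0
quercetin 3-O-glucoside,C21H20O12,flavonol,0
kaempferol,C15H10O6,flavonol,0
kaempferol 3-O-glucoside,C21H20O11,flavonol,0
myricetin,C15H10O8,flavonol,0
malvidin 3-O-glucoside,C23H25O12,anthocyanin,1
peonidin 3-O-glucoside,C22H23O11,anthocyanin,1
pelargonidin 3-O-glucoside,C21H21O10,anthocyanin,1
cyanidin 3-O-glucoside,C21H21O11,anthocyanin,1
delphinidin 3-O-glucoside,C21H21O12,anthocyanin,1
petunidin 3-O-glucoside,C22H23O12,anthocyanin,1
gallic acid,C7H6O5,phenolic acid,0
caffeic acid,C9H8O4,phenolic acid,0
p-coumaric acid,C9H8O3,phenolic acid,0
ferulic acid,C10H10O4,phenolic acid,0
syringic acid,C9H10O5,phenolic acid,0
caftaric acid,C13H12O9,phenolic acid,0
resveratrol,C14H12O3,stilbene,0
piceid,C20H22O8,stilbene,0
ellagic acid,C14H6O8,ellagitannin,0
tartaric acid,C4H6O6,organic acid,0
malic acid,C4H6O5,organic acid,0
citric acid,C6H8O7,organic acid,0
succinic acid,C4H6O4,organic acid,0
amygdalin,C20H27NO11,cyanogenic glucoside,0
prunasin,C14H17NO6,cyanogenic glucoside,0
4-ethylphenol,C8H10O,phenol,0
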