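# Pharmacophore feature perception rules (editable).
#
# Six feature kinds: hydrogen-bond acceptor (A), hydrogen-bond donor (D),
# hydrophobic group (H), negative ionizable (N), positive ionizable (P),
# aromatic ring (R).  A/D/N/P are per-atom SMARTS matches; H matches atoms
# that are then clustered into connected hydrophobic groups (one site per
# group centroid); R is perceived from aromatic ring systems (one site per
# ring centroid, with the ring normal as direction).
version: 1
acceptor:
  - "[OX1;+0]"                 # carbonyl / N-oxide terminal oxygen
  - "[OX2;H0;+0;!$(O=*)]"      # ether / ester oxygen
  - "[OX2;H1;+0]"              # hydroxyl oxygen
  - "[NX1]"                    # nitrile nitrogen
  - "[n;X2;H0;+0]"             # pyridine-type aromatic nitrogen
donor:
  - "[#7;!H0]"                 # N-H (neutral or charged)
  - "[OX2;H1]"                 # O-H
  - "[SX2;H1]"                 # S-H
positive:
  - "[N;+1;!$([N+]~[O-])]"     # formally positive nitrogen (not nitro/N-oxide)
  - "[NX3;H2,H1;+0;!$(N-a);!$(N-C=[O,N,S]);!$(N=*);!$(N-[O,N])]"  # basic amine
negative:
  - "[O-,S-;X1]"               # formally negative chalcogen
  - "[N-;X2]"                  # deprotonated amide/azole nitrogen
  - "[OX2H1;$(O-C=O)]"         # carboxylic acid O-H (ionizable)
hydrophobic:
  - "[CX4;!$(C[#7,#8,#9,#15,#16,#17,#35,#53])]"  # aliphatic C with no polar neighbour
  - "[Cl,Br,I]"                # heavy halogens
hydrophobic_min_group: 1
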