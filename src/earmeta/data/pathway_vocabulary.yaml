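# Default pathway-keyword vocabulary for candidate-gene prioritization.
#
# Each key names one of the molecular modules known to regulate maize female
# inflorescence development; the keywords are matched case-insensitively as
# substrings against gene annotation text.  Users may override or extend this
# file (pathway -> list of keywords).
auxin:
  - auxin
  - YUCCA
  - PIN
  - AUX/IAA
  - ARF
  - TAA
  - PINOID
  - tryptophan aminotransferase
TALE:
  - KNOX
  - homeobox
  - BELL
  - TALE
  - KNOTTED
CLV-WUS:
  - CLAVATA
  - CLE
  - WUSCHEL
  - CORYNE
  - receptor kinase
  - receptor-like protein
ROS:
  - glutaredoxin
  - malate transporter
  - metalloprotease
  - bZIP
RA:
  - zinc finger
  - LOB domain
  - trehalose-6-phosphate
  - SBP-box
  - HD-Zip
ethylene:
  - ACC oxidase
  - aminocyclopropane
  - ERF
  - ethylene-responsive
  - AP2
miR172:
  - AP2
  - APETALA2
WD40:
  - WD40
  - WD repeat
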