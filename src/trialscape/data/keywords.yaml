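# Default primary-sponsor classification keywords.
# Matching is case-insensitive. Tokens of at most `short_token_max`
# characters are matched with word boundaries (so "inc" hits "Acme Inc."
# but not "Incorporated research network of hospitals" is still fine
# because longer keywords use plain substring matching).
short_token_max: 4
industry:
  - inc
  - ltd
  - llc
  - plc
  - gmbh
  - corp
  - corporation
  - pharma
  - pharmaceutical
  - pharmaceuticals
  - biotech
  - biosciences
  - therapeutics
  - laboratories
  - s.a.
  - ag
non_industry:
  - university
  - universite
  - universitat
  - hospital
  - hopital
  - institute
  - institut
  - college
  - ministry
  - council
  - medical center
  - medical centre
  - school of medicine
  - academy
  - nih
  - inserm
  - charite
  - clinic
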