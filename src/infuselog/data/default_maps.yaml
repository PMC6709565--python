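# Default free-text normalisation maps.
#
# Care-area synonyms: the NICU list covers the profile-name variants known to
# occur in multilingual European drug libraries (neonatal units, intensive
# care nurseries, special care baby units / nurseries). The PICU / GICU / CICU
# stem lists are supplied by this package: institutions label those profiles
# far less consistently and no authoritative synonym table exists, so extend
# these lists in a site-local YAML rather than editing code.
#
# Matching is case-folded substring matching, longest stem first.
care_area_map:
  NICU:
    - nicu
    - neonat          # "Neonatal", "Neonates <2 kg", "NEONATOLOGIE"
    - scbu            # special care baby unit
    - special care baby
    - scn             # special care nursery
    - special care nursery
    - icn             # intensive care nursery
    - intensive care nursery
  PICU:
    - picu
    - paediatric intensive
    - pediatric intensive
    - paeds icu
    - peds icu
  GICU:
    - gicu
    - general intensive
    - general icu
    - adult intensive
    - adult icu
    - general critical
  CICU:
    - cicu
    - ccu
    - coronary
    - cardiac intensive
    - cardiac icu
    - cardiothoracic

# Drug stems for the four critical short half-life (CSHL) infusions studied.
# Glyceryl trinitrate (GTN/NTG) is deliberately absent: it falls to OTHER.
drug_map:
  ADRENALINE:
    - adrenalin
    - epinephrin
  NORADRENALINE:
    - noradrenalin
    - norepinephrin
    - levophed
  DOBUTAMINE:
    - dobutamin
  DOPAMINE:
    - dopamin

# Plasma half-lives in seconds, [min, max].
half_lives:
  ADRENALINE: [180, 180]
  DOBUTAMINE: [120, 120]
  DOPAMINE: [60, 120]
  NORADRENALINE: [120, 180]
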