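# Default health-reference lexicon for the ndchealth scoring rubric.
#
# core_terms trigger candidate detection: any sentence containing at least one
# of them is a candidate health reference. The cue lists then decide the
# category, one list per (group, level). Terms are normalized with the same
# rules as corpus text (lowercase, accents folded, intra-word hyphens
# collapsed), so "co-benefits" here matches "co-benefits" in a document.
# Multiword terms match as contiguous phrases on unfiltered sentence tokens.
#
# This list is an editable, versioned stand-in developed against the category
# definitions of the scoring rubric; pass your own YAML to
# HealthLexicon.from_yaml to replace it.

core_terms:
  - health
  - healthy
  - healthcare
  - health-care
  - disease
  - diseases
  - illness
  - illnesses
  - well-being
  - wellbeing
  - mortality
  - morbidity
  - epidemic
  - epidemics
  - pandemic
  - malaria
  - dengue
  - cholera
  - malnutrition
  - sanitation
  - hygiene
  - save lives
  - saving lives
  - life expectancy

cues:
  # Effect of climate change on health / the health sector.
  impact/general:
    - impact
    - impacts
    - effect
    - effects
    - affect
    - affects
    - affected
    - consequence
    - consequences
    - harm
    - harms
    - threat
    - threats
    - exposure
  # Specific health outcomes named (level cue on top of any impact reading).
  impact/specific:
    - death
    - deaths
    - injury
    - injuries
    - psychological
    - disorder
    - disorders
    - disease
    - diseases
    - malaria
    - dengue
    - cholera
    - diarrhoea
    - diarrhea
    - malnutrition
    - stunting
    - heat stress
    - heatstroke
    - mortality
    - morbidity
    - respiratory
    - cardiovascular
    - vector-borne
    - water-borne
    - waterborne
  # Need for adaptation touching health.
  adaptation/general:
    - adaptation
    - adaptations
    - adapt
    - adapting
    - resilience
    - resilient
    - vulnerability
    - vulnerable
    - risk
    - risks
  # Specific health outcome inside an adaptation reading.
  adaptation/specific:
    - death
    - deaths
    - injury
    - injuries
    - disease
    - diseases
    - malaria
    - dengue
    - cholera
    - diarrhoea
    - diarrhea
    - malnutrition
    - heat stress
    - mortality
    - morbidity
    - vector-borne
  # Plan-operational vocabulary marking detailed adaptation provisions.
  adaptation/detailed:
    - monitoring
    - early warning
    - early-warning
    - surveillance
    - strengthen
    - strengthening
    - risk monitoring
    - response systems
    - preparedness
    - contingency plan
  # Link between health and mitigation measures/sectors.
  mitigation/general:
    - mitigation
    - emission
    - emissions
    - energy
    - renewable
    - waste
    - fuel
    - fuels
    - electricity
    - low carbon
    - decarbonisation
    - decarbonization
  # Measures with joint climate and health gains.
  co_benefit/general:
    - co-benefit
    - co-benefits
    - cobenefit
    - cobenefits
    - cooking
    - cookstove
    - cookstoves
    - clean cooking
    - air quality
    - active transport
    - cycling
  # Named specific health benefit of the measure.
  co_benefit/specific:
    - lives
    - save lives
    - deaths
    - premature
    - respiratory
    - cardiovascular
    - asthma
  # Financial trade-offs between health/development spending and climate action.
  trade_off/general:
    - fiscal
    - constrains
    - constraint
    - constraints
    - trade-off
    - trade-offs
    - tradeoff
    - tradeoffs
    - burden
    - competing priorities
    - diverts
  # Country health-profile / development-challenge background description.
  background/general:
    - challenge
    - challenges
    - poverty
    - development challenges
    - profile
    - illiteracy
    - socioeconomic
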