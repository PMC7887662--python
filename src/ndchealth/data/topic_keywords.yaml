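# Default theme keywords for the keyword-assisted topic model: four keyed
# themes (health, economics, energy, agriculture); residual topics absorb the
# rest. Lists are editable stand-ins developed for English climate-pledge
# vocabulary; keywords must be disjoint across topics.
health:
  - health
  - disease
  - diseases
  - malaria
  - nutrition
  - sanitation
  - hospital
  - epidemic
economics:
  - economy
  - economic
  - gdp
  - growth
  - finance
  - investment
  - trade
  - fiscal
energy:
  - energy
  - electricity
  - renewable
  - solar
  - fuel
  - power
  - grid
  - emissions
agriculture:
  - agriculture
  - agricultural
  - crop
  - crops
  - livestock
  - farming
  - food
  - irrigation
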