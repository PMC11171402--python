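# Agonistic-behavior ethogram of Litopenaeus vannamei: nine mutually
# exclusive behavior patterns grouped into three fighting stages.
name: vannamei_agonistic
states:
  - {name: parade, label: Parade}
  - {name: demonstration, label: Demonstration}
  - {name: attack, label: Attack}
  - {name: fight, label: Fight}
  - {name: chase, label: Chase}
  - {name: impact, label: Impact}
  - {name: feint, label: Feint}
  - {name: temporary retreat, label: Temporary retreat}
  - {name: retreat, label: Retreat}
stages:
  encounter: [parade, demonstration]
  contact: [attack, fight, chase, impact, feint]
  withdrawal: [temporary retreat, retreat]
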