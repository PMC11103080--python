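annotators:
- id: E01
  role: human
- id: E02
  role: human
- id: E03
  role: human
- id: E04
  role: human
- id: E05
  role: human
- id: E06
  role: human
- id: E07
  role: human
- id: E08
  role: human
- id: E09
  role: human
- id: E10
  role: human
- id: E11
  role: human
- id: E12
  role: human
- id: E13
  role: human
- id: E14
  role: human
- id: E15
  role: human
- id: E16
  role: human
- id: E17
  role: human
- id: E18
  role: human
- id: E19
  role: human
- id: AI
  role: ai
scans:
- id: isb_01
  region: ISB
  width: 512
  height: 384
- id: isb_02
  region: ISB
  width: 512
  height: 384
- id: isb_03
  region: ISB
  width: 512
  height: 384
- id: isb_04
  region: ISB
  width: 512
  height: 384
- id: isb_05
  region: ISB
  width: 512
  height: 384
- id: axb_01
  region: AxB
  width: 512
  height: 384
- id: axb_02
  region: AxB
  width: 512
  height: 384
- id: axb_03
  region: AxB
  width: 512
  height: 384
- id: axb_04
  region: AxB
  width: 512
  height: 384
- id: axb_05
  region: AxB
  width: 512
  height: 384
- id: espb_01
  region: ESPB
  width: 512
  height: 384
- id: espb_02
  region: ESPB
  width: 512
  height: 384
- id: espb_03
  region: ESPB
  width: 512
  height: 384
- id: espb_04
  region: ESPB
  width: 512
  height: 384
- id: espb_05
  region: ESPB
  width: 512
  height: 384
- id: rsb_01
  region: RSB
  width: 512
  height: 384
- id: rsb_02
  region: RSB
  width: 512
  height: 384
- id: rsb_03
  region: RSB
  width: 512
  height: 384
- id: rsb_04
  region: RSB
  width: 512
  height: 384
- id: rsb_05
  region: RSB
  width: 512
  height: 384
- id: acb_01
  region: ACB
  width: 512
  height: 384
- id: acb_02
  region: ACB
  width: 512
  height: 384
- id: acb_03
  region: ACB
  width: 512
  height: 384
- id: acb_04
  region: ACB
  width: 512
  height: 384
- id: acb_05
  region: ACB
  width: 512
  height: 384
- id: snb_01
  region: SNB
  width: 512
  height: 384
- id: snb_02
  region: SNB
  width: 512
  height: 384
- id: snb_03
  region: SNB
  width: 512
  height: 384
- id: snb_04
  region: SNB
  width: 512
  height: 384
- id: snb_05
  region: SNB
  width: 512
  height: 384
structures:
- id: c5_root
  name: C5 nerve root
  region: ISB
  class: nerve
  kind: region
- id: c6_root
  name: C6 nerve root
  region: ISB
  class: nerve
  kind: region
- id: scalenus_anterior
  name: Scalenus anterior
  region: ISB
  class: muscle
  kind: region
- id: scalenus_medius
  name: Scalenus medius
  region: ISB
  class: muscle
  kind: region
- id: axillary_artery
  name: Axillary artery
  region: AxB
  class: artery
  kind: region
- id: median_nerve
  name: Median nerve
  region: AxB
  class: nerve
  kind: region
- id: musculocutaneous_nerve
  name: Musculocutaneous nerve
  region: AxB
  class: nerve
  kind: region
- id: radial_nerve
  name: Radial nerve
  region: AxB
  class: nerve
  kind: region
- id: ulnar_nerve
  name: Ulnar nerve
  region: AxB
  class: nerve
  kind: region
- id: conjoint_tendon_fascia
  name: Fascia over conjoint tendon
  region: AxB
  class: fascia_serosa
  kind: line
- id: es_muscle_group
  name: Erector spinae muscle group
  region: ESPB
  class: muscle
  kind: region
- id: transverse_process
  name: Transverse process
  region: ESPB
  class: fascia_serosa
  kind: line
- id: pleura
  name: Pleura
  region: ESPB
  class: fascia_serosa
  kind: line
  quantitative: false
- id: rectus_abdominis
  name: Rectus abdominis
  region: RSB
  class: muscle
  kind: region
- id: rectus_sheath_anterior
  name: Rectus sheath (anterior layer)
  region: RSB
  class: fascia_serosa
  kind: line
- id: rectus_sheath_posterior
  name: Rectus sheath (posterior layer)
  region: RSB
  class: fascia_serosa
  kind: line
- id: peritoneum
  name: Peritoneum
  region: RSB
  class: fascia_serosa
  kind: line
- id: femoral_artery
  name: Femoral artery
  region: ACB
  class: artery
  kind: region
- id: saphenous_nerve
  name: Saphenous nerve
  region: ACB
  class: nerve
  kind: region
- id: sartorius
  name: Sartorius
  region: ACB
  class: muscle
  kind: region
- id: sciatic_nerve
  name: Sciatic nerve
  region: SNB
  class: nerve
  kind: region
grouping:
  c5_root: c5_c6
  c6_root: c5_c6
  rectus_sheath_anterior: rectus_sheath
  rectus_sheath_posterior: rectus_sheath
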