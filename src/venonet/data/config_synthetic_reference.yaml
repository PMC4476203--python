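reference_nodes:
- subclavian
- right_atrium
viscosity_cP: 3.0
flow_inputs:
- node: cerebral_inlet
  label: Q_c
  ml_per_s: 12.0
- node: cervical_plexus_1
  label: Q_v1
  ml_per_s: 0.3
- node: cervical_plexus_2
  label: Q_v2
  ml_per_s: 0.3
- node: cervical_plexus_3
  label: Q_v3
  ml_per_s: 0.3
- node: cervical_plexus_4
  label: Q_v4
  ml_per_s: 0.3
- node: cervical_plexus_5
  label: Q_v5
  ml_per_s: 0.3
- node: cervical_plexus_6
  label: Q_v6
  ml_per_s: 0.3
- node: cervical_plexus_7
  label: Q_v7
  ml_per_s: 0.3
- node: thoracic_plexus_1
  label: Q_v8
  ml_per_s: 0.4
- node: thoracic_plexus_2
  label: Q_v9
  ml_per_s: 0.4
- node: thoracic_plexus_3
  label: Q_v10
  ml_per_s: 0.4
- node: thoracic_plexus_4
  label: Q_v11
  ml_per_s: 0.4
- node: thoracic_plexus_5
  label: Q_v12
  ml_per_s: 0.4
- node: thoracic_plexus_6
  label: Q_v13
  ml_per_s: 0.4
- node: thoracic_plexus_7
  label: Q_v14
  ml_per_s: 0.4
- node: thoracic_plexus_8
  label: Q_v15
  ml_per_s: 0.4
- node: thoracic_plexus_9
  label: Q_v16
  ml_per_s: 0.4
- node: thoracic_plexus_10
  label: Q_v17
  ml_per_s: 0.4
- node: thoracic_plexus_11
  label: Q_v18
  ml_per_s: 0.4
- node: thoracic_plexus_12
  label: Q_v19
  ml_per_s: 0.4
- node: lumbar_plexus_1
  label: Q_v20
  ml_per_s: 0.8
- node: lumbar_plexus_2
  label: Q_v21
  ml_per_s: 0.8
- node: femoral
  label: Q_f
  ml_per_s: 10.0
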