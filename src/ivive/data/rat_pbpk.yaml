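# Representative rat whole-body parameter set for amiodarone (0.25 kg
# animal), assembled from standard rat physiological reference values with
# the same compound binding assumptions as the human fixture.  Documented
# representative values for the interspecies branch of the pipeline; not a
# reprint of any single published table.
schema: ivive-pbpk-1
species: rat
description: representative 0.25 kg rat, amiodarone
body_weight_kg: 0.25
cardiac_output_L_per_h: 5.04
blood:
  volume_arterial_L: 0.0045
  volume_venous_L: 0.0113
compound:
  name: amiodarone
  molecular_weight_g_per_mol: 645.31
  fu_plasma: 0.06
  blood_plasma_ratio: 0.73
hepatic_clearance_L_per_h: 5.0
eliminating_tissue: liver
lung:
  volume_vascular_L: 0.0009
  volume_tissue_L: 0.0015
  ps_L_per_h: 0.8
  fu_tissue: 0.001
tissues:
  brain:
    volume_vascular_L: 0.0002
    volume_tissue_L: 0.0018
    blood_flow_L_per_h: 0.10
    ps_L_per_h: 0.0006
    fu_tissue: 0.0001
  heart:
    volume_vascular_L: 0.0002
    volume_tissue_L: 0.0010
    blood_flow_L_per_h: 0.25
    ps_L_per_h: 0.4
    fu_tissue: 0.005
  liver:
    volume_vascular_L: 0.0018
    volume_tissue_L: 0.0092
    blood_flow_L_per_h: 0.91
    ps_L_per_h: 2.0
    fu_tissue: 0.0005
  kidney:
    volume_vascular_L: 0.0004
    volume_tissue_L: 0.0020
    blood_flow_L_per_h: 0.70
    ps_L_per_h: 0.8
    fu_tissue: 0.002
  muscle:
    volume_vascular_L: 0.0030
    volume_tissue_L: 0.1220
    blood_flow_L_per_h: 1.41
    ps_L_per_h: 1.6
    fu_tissue: 0.004
  skin:
    volume_vascular_L: 0.0005
    volume_tissue_L: 0.0190
    blood_flow_L_per_h: 0.30
    ps_L_per_h: 0.4
    fu_tissue: 0.004
  adipose:
    volume_vascular_L: 0.0005
    volume_tissue_L: 0.0190
    blood_flow_L_per_h: 0.35
    ps_L_per_h: 0.5
    fu_tissue: 0.0003
  gut:
    volume_vascular_L: 0.0007
    volume_tissue_L: 0.0067
    blood_flow_L_per_h: 0.70
    ps_L_per_h: 0.8
    fu_tissue: 0.002
  spleen:
    volume_vascular_L: 0.0001
    volume_tissue_L: 0.0006
    blood_flow_L_per_h: 0.05
    ps_L_per_h: 0.2
    fu_tissue: 0.002
  rest_of_body:
    volume_vascular_L: 0.0005
    volume_tissue_L: 0.0050
    blood_flow_L_per_h: 0.27
    ps_L_per_h: 0.6
    fu_tissue: 0.002
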