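# Brain-energetics metabolic tasks for the packaged toy network.
# Each task: can the model produce the outputs (minimum amounts) from the
# inputs (maximum uptakes) with all other exchanges closed?  Outputs with a
# 0 minimum are permitted byproduct secretions.
- id: atp_aerobic_glucose
  description: ATP regeneration from glucose with oxygen available
  inputs: {glc_e: 1, o2_e: 100, adp_c: 1000}
  outputs: {atp_c: 20, co2_e: 0, h2o_e: 0, lac_e: 0}
- id: atp_anaerobic_glucose
  description: substrate-level ATP from glucose without oxygen
  inputs: {glc_e: 1, adp_c: 1000}
  outputs: {atp_c: 2, lac_e: 0}
- id: atp_from_fatty_acid
  description: ATP from a palmitate-like fatty acid via beta-oxidation
  inputs: {fa_e: 1, o2_e: 100, adp_c: 1000}
  outputs: {atp_c: 50, co2_e: 0, h2o_e: 0}
- id: atp_from_glutamate
  description: ATP from glutamate anaplerosis into the TCA cycle
  inputs: {glu_e: 1, o2_e: 100, adp_c: 1000}
  outputs: {atp_c: 5, co2_e: 0, h2o_e: 0, nh4_e: 0}
- id: lactate_secretion
  description: aerobic glycolysis endpoint, lactate export
  inputs: {glc_e: 1}
  outputs: {lac_e: 1.5}
- id: cytosolic_nadh_reoxidation
  description: reoxidize cytosolic NADH through the shuttles and the chain
  inputs: {nadh_c: 1, o2_e: 10}
  outputs: {nad_c: 1, h2o_e: 0}
- id: mitochondrial_nadh_reoxidation
  description: reoxidize matrix NADH through complex I
  inputs: {nadh_m: 1, o2_e: 10}
  outputs: {nad_m: 1, h2o_e: 0}
- id: glucose_complete_oxidation
  description: full oxidation of glucose to CO2
  inputs: {glc_e: 1, o2_e: 6}
  outputs: {co2_e: 6, h2o_e: 0}
- id: glutamate_anaplerosis
  description: glutamate carbon enters the TCA cycle and leaves as CO2
  inputs: {glu_e: 1, o2_e: 100}
  outputs: {co2_e: 2, h2o_e: 0, nh4_e: 0}
- id: phosphocreatine_buffer
  description: ATP buffering through creatine kinase
  inputs: {pcr_e: 1, adp_c: 10}
  outputs: {atp_c: 1, cr_e: 0}
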