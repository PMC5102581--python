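# Packaged uricase case-study configuration.
# Flowsheet step yields are stored at full precision so the composite
# DSP yields equal exactly 0.432 (chromatography) and 0.66 (ATPS).
flowsheets:
- process_id: chromatography
  fermenter_volume: 25.0
  titer: 0.484
  operations:
  - name: E. coli fermentation
    category: fermentation
    step_yield: 1.0
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: biomass recovery centrifuge
    category: centrifugation
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: high-pressure homogenizer
    category: homogenization
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: debris removal centrifuge
    category: centrifugation
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: chromatography column 1
    category: chromatography
    step_yield: 0.8094619555827783
    volume_factor: 1.0
    material_items: []
    consumable_items:
    - resin
  - name: chromatography column 2
    category: chromatography
    step_yield: 0.8094619555827783
    volume_factor: 1.0
    material_items: []
    consumable_items:
    - resin
  - name: chromatography column 3
    category: chromatography
    step_yield: 0.8094619555827783
    volume_factor: 1.0
    material_items: []
    consumable_items:
    - resin
  - name: UF/DF concentration & buffer exchange
    category: ufdf
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items:
    - ufdf_filters
- process_id: atps
  fermenter_volume: 25.0
  titer: 0.484
  operations:
  - name: E. coli fermentation
    category: fermentation
    step_yield: 1.0
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: biomass recovery centrifuge
    category: centrifugation
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: high-pressure homogenizer
    category: homogenization
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: debris removal centrifuge
    category: centrifugation
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: ATPS extraction
    category: atps
    step_yield: 0.8103068576821849
    volume_factor: 4.800000000000001
    material_items:
    - peg2000
    - ammonium_sulfate
    - nacl
    consumable_items: []
  - name: UF/DF concentration & buffer exchange
    category: ufdf
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items:
    - ufdf_filters
- process_id: atps_recycle
  fermenter_volume: 25.0
  titer: 0.484
  operations:
  - name: E. coli fermentation
    category: fermentation
    step_yield: 1.0
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: biomass recovery centrifuge
    category: centrifugation
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: high-pressure homogenizer
    category: homogenization
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: debris removal centrifuge
    category: centrifugation
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items: []
  - name: ATPS extraction
    category: atps
    step_yield: 0.8103068576821849
    volume_factor: 4.800000000000001
    material_items:
    - peg2000
    - ammonium_sulfate
    - nacl
    consumable_items: []
  - name: back-extraction (second ATPS)
    category: back_extraction
    step_yield: 1.0
    volume_factor: 2.083333333333333
    material_items:
    - ammonium_sulfate
    consumable_items: []
  - name: UF/DF concentration & buffer exchange
    category: ufdf
    step_yield: 0.95
    volume_factor: 1.0
    material_items: []
    consumable_items:
    - ufdf_filters
cost_model:
  target_output_g_per_year: 100.0
  batches_continuous: true
  ufdf_filter_capacity_l: 50.0
  ufdf_filter_cost_usd: 1100.0
  labor_base_location: UK
  labor_wages:
    UK:
      production_operator: 32935.0
      production_supervisor: 38490.0
      quality_assurance: 56176.0
      qc: 31400.0
    Mexico:
      production_operator: 41872.0
      production_supervisor: 52337.0
      quality_assurance: 70149.0
      qc: 39101.0
    USA:
      production_operator: 37689.0
      production_supervisor: 37689.0
      quality_assurance: 35995.0
      qc: 35995.0
  scenario_material_items:
  - media
  - peg2000
  - ammonium_sulfate
  - nacl
  - ufdf_filters
  material_lines:
    chromatography:
      media: 1800.0
    atps:
      media: 1800.0
      peg2000: 3600.0
      ammonium_sulfate: 1100.0
      nacl: 300.0
  calibration:
    chromatography:
      target_cog_usd_per_g: 9396.97
      shares:
        capital: 0.32
        materials: 0.1
        consumables: 0.25
        labor: 0.13
        other: 0.2
    atps:
      target_cog_usd_per_g: 5452.0
      shares:
        capital: 0.25
        materials: 0.3
        consumables: 0.18
        labor: 0.13
        other: 0.14
atps:
  system_volume_multiplier: 12.0
  top_fraction: 0.4
  product_destination: top
  component_charge_per_sample_l:
    peg2000: 1.8
    ammonium_sulfate: 1.6
    nacl: 0.96
  top_split:
    peg2000: 0.65
    ammonium_sulfate: 0.35
    nacl: 0.5
recycle:
  r_peg: 0.6
  r_as: 0.2
  r_nacl: 0.2
  bottom_fraction_second_system: 0.56
  fresh_as_per_sample_l: 0.8266666666666667
scenarios:
- variable: titer
  best: 0.577
  base: 0.484
  worst: 0.392
- variable: dsp_yield
  best: 10.0
  base: 0.0
  worst: -10.0
- variable: material_cost
  best: 0.75
  base: 1.0
  worst: 1.25
- variable: labor_location
  best: Mexico
  base: UK
  worst: USA
distributions:
  titer:
    low: 0.392
    mode: 0.484
    high: 0.577
  dsp_yield_delta:
    low: -10.0
    mode: 0.0
    high: 10.0
monte_carlo:
  n_max: 1000
  window: 50
  tol: 0.005
overlap:
  n: 100000
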