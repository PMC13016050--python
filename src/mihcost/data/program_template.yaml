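elements:
- id: personnel_paramedics
  label: 'Personnel salaries with fringe: paramedics (6.5 FTE)'
  classification: fixed
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 480000.0
    mode: 552000.0
    max: 650000.0
- id: personnel_administrator
  label: 'Personnel salaries with fringe: program administrator (1.0 FTE)'
  classification: fixed
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 70000.0
    mode: 85000.0
    max: 102000.0
- id: personnel_physician
  label: 'Personnel salaries with fringe: physician medical direction (0.5 FTE)'
  classification: fixed
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 90000.0
    mode: 110000.0
    max: 135000.0
- id: administrative
  label: 'Administrative: state license fees, paramedic certification fees, continuing
    education courses, operational software'
  classification: fixed
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 15000.0
    mode: 25000.0
    max: 40000.0
- id: equipment
  label: 'Non-disposable clinical equipment (annualized): cardiac monitors, point-of-care
    blood machine, laptop computers, portable printers, radios, WIFI hotspot, clinical
    software'
  classification: fixed
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 40000.0
    mode: 60000.0
    max: 90000.0
- id: fuel
  label: Fuel
  classification: variable
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 8000.0
    mode: 12000.0
    max: 18000.0
- id: vehicle_maintenance
  label: Vehicle maintenance
  classification: variable
  basis: per_period
  applicability: all
  reimbursable: false
  pert:
    min: 5000.0
    mode: 9000.0
    max: 15000.0
- id: laboratory_analysis_basic
  label: Laboratory analysis per basic visit (unit cost x mean panels)
  classification: variable
  basis: per_visit
  applicability: basic_only
  reimbursable: true
  pert:
    min: 12.0
    mode: 30.0
    max: 65.0
- id: radiology_basic
  label: Radiology studies and interpretation per basic visit
  classification: variable
  basis: per_visit
  applicability: basic_only
  reimbursable: true
  pert:
    min: 8.0
    mode: 22.0
    max: 55.0
- id: medications_supplies_basic
  label: Oral medications, prescriptions and clinical supplies per basic visit
  classification: variable
  basis: per_visit
  applicability: basic_only
  reimbursable: false
  pert:
    min: 20.0
    mode: 48.0
    max: 95.0
- id: laboratory_analysis_advanced
  label: Laboratory analysis per advanced visit (unit cost x mean panels)
  classification: variable
  basis: per_visit
  applicability: advanced_only
  reimbursable: true
  pert:
    min: 120.0
    mode: 250.0
    max: 450.0
- id: radiology_advanced
  label: Radiology studies and interpretation per advanced visit
  classification: variable
  basis: per_visit
  applicability: advanced_only
  reimbursable: true
  pert:
    min: 280.0
    mode: 560.0
    max: 950.0
- id: iv_medications_supplies
  label: IV medications and fluids with administration supplies per advanced visit
  classification: variable
  basis: per_visit
  applicability: advanced_only
  reimbursable: false
  pert:
    min: 55.0
    mode: 115.0
    max: 210.0
visit_mix:
  annual_visits:
    min: 700.0
    mode: 800.0
    max: 900.0
  prop_basic: 0.6
  prop_advanced: 0.4
simulation:
  iterations: 1000
  interval_level: 0.9
  seed: 1
  pert_shape: 4.0
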