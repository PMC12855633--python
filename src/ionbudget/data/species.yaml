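# Default chemical registry for ionbudget.
# molar_mass in g/mol of the species; element masses in g/mol of the element.
# Charges are the ionic charges assumed for charge-equivalent (mmol_IE) bookkeeping;
# metals measured as elements are assumed fully ionic (Al as Al3+ etc.).
elements:
  H: 1.008
  N: 14.007
  S: 32.06
  Cl: 35.45
  Ca: 40.078
  Mg: 24.305
  K: 39.098
  Na: 22.990
  Al: 26.982
  Mn: 54.938
  Fe: 55.845
species:
  - {name: H,   formula: "H+",    molar_mass: 1.008,  charge: 1,  element: H,  element_stoichiometry: 1}
  - {name: NH4, formula: "NH4+",  molar_mass: 18.039, charge: 1,  element: N,  element_stoichiometry: 1}
  - {name: NO3, formula: "NO3-",  molar_mass: 62.004, charge: -1, element: N,  element_stoichiometry: 1}
  - {name: SO4, formula: "SO4-2", molar_mass: 96.06,  charge: -2, element: S,  element_stoichiometry: 1}
  - {name: Cl,  formula: "Cl-",   molar_mass: 35.45,  charge: -1, element: Cl, element_stoichiometry: 1}
  - {name: Ca,  formula: "Ca+2",  molar_mass: 40.078, charge: 2,  element: Ca, element_stoichiometry: 1}
  - {name: Mg,  formula: "Mg+2",  molar_mass: 24.305, charge: 2,  element: Mg, element_stoichiometry: 1}
  - {name: K,   formula: "K+",    molar_mass: 39.098, charge: 1,  element: K,  element_stoichiometry: 1}
  - {name: Na,  formula: "Na+",   molar_mass: 22.990, charge: 1,  element: Na, element_stoichiometry: 1}
  - {name: Al,  formula: "Al+3",  molar_mass: 26.982, charge: 3,  element: Al, element_stoichiometry: 1}
  - {name: Mn,  formula: "Mn+2",  molar_mass: 54.938, charge: 2,  element: Mn, element_stoichiometry: 1}
  - {name: Fe,  formula: "Fe+3",  molar_mass: 55.845, charge: 3,  element: Fe, element_stoichiometry: 1}
# Emission gases on a molecule-molar basis; NOx is expressed as NO2 (standard
# inventory convention, overridable).
gases:
  SO2: 64.07
  NH3: 17.031
  NOx: 46.006
  NO2: 46.006
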