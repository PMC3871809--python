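# Default parameter set for the kiwifruit berry model.
# Units are given per field; values are the base parameterization for a
# low crop-load 'Hayward' kiwifruit berry.

initial:            # state at the start of the simulation (t_start DAFB)
  w0: 3.2           # g, initial water mass
  s0: 0.5           # g, initial dry mass
  u0: 0.01          # g, initial starch mass
  Pf0: 2.0          # bar, initial turgor

solutes:            # osmotic contribution of solutes other than sugars
  pi_pO: 12.53      # bar, in the phloem sap
  pi_fO: 6.5        # bar, in the fruit

expansion:          # turgor-driven wall expansion (Lockhart/Ortega)
  Y: 2.0            # bar, yield threshold
  d1: 15.0          # DAFB, end of the cell-division extensibility plateau
  d2: 60.0          # DAFB, end of the log-linear extensibility transition
  phi1: 0.2         # bar^-1 h^-1, extensibility in the cell-division phase
  phi2: 0.00135     # bar^-1 h^-1, extensibility at d2
  phi_k: 0.0028     # d^-1, late-season decline rate of ln(phi)
  epsilon: 153.0    # bar, volumetric elastic modulus

uptake:             # Michaelis-Menten active sugar uptake
  Km: 0.08          # g/g, Michaelis constant (mass fraction)
  nu1: 0.005        # h^-1, uptake scale per g dry mass at 20 C
  Q10_nu: 2.0       # dimensionless, temperature coefficient

membrane:           # composite membrane between vasculature and fruit
  sigma_p: 0.9      # reflection coefficient, phloem pathway
  sigma_x: 1.0      # reflection coefficient, xylem pathway
  a_x: 0.066        # fraction of fruit surface area, xylem membrane
  a_p: 0.066        # fraction of fruit surface area, phloem membrane
  L_x: 0.0072       # g cm^-2 bar^-1 h^-1, hydraulic conductivity (xylem)
  L_p: 0.0072       # g cm^-2 bar^-1 h^-1, hydraulic conductivity (phloem)
  p_s: 0.003        # cm h^-1, solute permeability

skin:               # skin permeance to water vapour, declining with age
  rho0: 800.0       # cm h^-1, permeance at t_rho
  rho_inf: 25.0     # cm h^-1, late-season asymptote
  k_rho: 0.035      # d^-1, decline rate
  t_rho: 18.0       # DAFB, first-datum anchor day

pedicel:            # axial conductances of the pedicel/receptacle conduit
  L1x: 0.09         # g h^-1 bar^-1, xylem conductance scale (rising phase)
  L2x: 0.02         # g h^-1 bar^-1, xylem late-season plateau
  k1x: 0.1          # d^-1, rise rate
  k2x: 0.036        # d^-1, decline rate
  t1: 30.0          # DAFB, rise midpoint
  t2: 70.0          # DAFB, decline midpoint
  Lp_inf: 0.016     # g h^-1 bar^-1, phloem conductance asymptote
  k1p: 0.1          # d^-1, phloem rise rate (matches k1x early on)

starch:             # starch <-> soluble solids sub-model
  A_o: 0.56         # proportion, structural-matter amplitude
  k_o: 0.0384       # g^-1, decay of structural proportion with dry mass
  s_b: 3.8          # %, basal soluble solids (of fresh weight)
  k_s1: 0.5         # d^-1, maximum starch synthesis rate
  t_r: 165.0        # DAFB, synthesis cutoff
  t_h: 25.0         # d, e-folding lead time of the synthesis decline
  k_u: 0.0551       # d^-1, starch breakdown rate

respiration:        # maintenance + growth respiration (peach-model values)
  q_m: 0.000444     # g g^-1 h^-1, maintenance coefficient at 20 C
  q_g: 0.084        # g/g, growth respiration per unit net growth
  Q10_r: 1.9        # dimensionless, temperature coefficient

constants:          # physical constants and fixed conventions
  R_g: 83.14        # cm^3 bar mol^-1 K^-1, gas constant
  M_s: 342.0        # g mol^-1, sucrose molar mass
  M_w: 18.0         # g mol^-1, water molar mass
  H_f: 0.996        # fraction, relative humidity of internal air spaces
  rho_sol: 1.0      # g cm^-3, solution density for mass-fraction -> molar
  density: 1.0      # g cm^-3, whole-fruit density (volume = FW / density)

area:               # fruit surface-area allometry A = gamma * FW^eta
  gamma: 5.2076     # cm^2 g^-eta
  eta: 0.6424       # dimensionless

options:            # model-form switches for under-determined pieces
  structural_form: proportion   # proportion | saturating  (o(s) functional form)
  cap_base: fresh               # fresh | juice            (basal-solubles cap basis)
  pedicel_sugar_conc: mean      # mean | downstream        (conc. in pedicel sugar flux)
  sensitivity_average: half_difference  # half_difference | abs_mean
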