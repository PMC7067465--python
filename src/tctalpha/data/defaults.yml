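# Default parameter set for the thalamo-cortico-thalamic (TCT) model.
#
# Connectivity constants C_xyz are dimensionless synaptic strengths,
# expressed as a percentage of the total number of synapses (T = 100)
# converging on the target population's dendritic terminal.  Subscript
# convention: x = postsynaptic (target) population, y = presynaptic
# (source) population, z = synapse type (e excitatory, i inhibitory).
# Population codes: t TCR, i IN, n TRN, p PY, x eIN, l sIN, f fIN,
# r retinal input, c cortico-cortical input, s self.
#
# Time constants are given in milliseconds and converted to seconds on
# load; all other units as annotated.

# --- thalamic module connectivity -------------------------------------
C_tre: 7.1     # retinal -> TCR (excitatory)
C_tii: 15.45   # IN -> TCR (inhibitory)
C_tni: 15.45   # TRN -> TCR (inhibitory)
C_tpe: 62.0    # PY -> TCR (excitatory)
C_ire: 47.4    # retinal -> IN (excitatory)
C_isi: 23.6    # IN -> IN self-inhibition
C_ipe: 29.0    # PY -> IN (excitatory)
C_nte: 35.0    # TCR -> TRN (excitatory)
C_nsi: 15.0    # TRN -> TRN self-inhibition
C_npe: 50.0    # PY -> TRN (excitatory)

# --- cortical module connectivity -------------------------------------
C_pce: 1.0     # cortico-cortical afferent -> PY (excitatory)
C_pte: 80.0    # TCR -> PY (excitatory)
C_pxe: 108.0   # eIN -> PY (excitatory)
C_pli: 33.75   # sIN -> PY (inhibitory)
C_pfi: 108.0   # fIN -> PY (inhibitory)
C_xte: 100.0   # TCR -> eIN (excitatory)
C_xpe: 135.0   # PY -> eIN (excitatory)
C_lte: 40.0    # TCR -> sIN (excitatory)
C_lpe: 33.75   # PY -> sIN (excitatory)
C_lfi: 13.5    # fIN -> sIN (inhibitory; cortical disinhibition pathway)
C_fte: 40.0    # TCR -> fIN (excitatory)
C_fpe: 40.5    # PY -> fIN (excitatory)
C_fli: 13.5    # sIN -> fIN (inhibitory)

# --- sigmoid (potential-to-rate) --------------------------------------
v: 0.56        # steepness, 1/mV
e0: 2.5        # half of the maximum discharge rate, spikes/s
s0: 6.0        # firing threshold, mV

# --- synaptic gains (mV) ----------------------------------------------
He_thal: 3.25  # excitatory gain, thalamic module
He_cort: 2.7   # excitatory gain, cortical module
Hi_thal: 22.0  # inhibitory gain, thalamic module (IN, TRN)
Hil: 4.5       # slow inhibitory gain, cortical module (sIN)
Hif: 39.0      # fast inhibitory gain, cortical module (fIN)

# --- PSP time constants (ms; converted to s on load) -------------------
tau_e_thal: 10.0
tau_e_cort: 25.0
tau_i: 25.0
tau_il: 50.0
tau_if: 3.0

# --- extrinsic drives (Gaussian white noise) ---------------------------
mu_r: 5.0      # retinal mean rate, spikes/s
phi_r: 0.05    # retinal variance, (spikes/s)^2
mu_c: 13.0     # cortico-cortical mean rate, spikes/s
phi_c: 0.05    # cortico-cortical variance, (spikes/s)^2
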