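# Desk-scale sweep configuration.  Every key is optional; omitted keys fall
# back to the defaults shown here.  Counts scale freely: a full-scale study
# (tens of thousands of sources, ~1000 patches) is the same file with
# bigger numbers.

# --- geometry -------------------------------------------------------------
n_sources: 600        # dipoles on the perturbed sphere
n_patches: 60         # disjoint patches tiling the surface
radius: 0.08          # reference sphere radius, metres
bumpiness: 0.1        # relative radial perturbation in [0, 0.5);
                      # keeps surface normals off-radial

# --- sensors --------------------------------------------------------------
n_sensors: 64
sensor_radius: 0.12   # metres; must exceed the largest source radius
modality: mag         # mag | grad | eeg (single label for all sensors)

# --- noise model ----------------------------------------------------------
noise_factors: 8      # rank of the spatially mixed background component
noise_scale: 1.0e-13  # RMS amplitude of the factor contribution, tesla
ar_coefficient: 0.95  # lag-1 autocorrelation of each background factor

# --- epoch bookkeeping ----------------------------------------------------
n_epochs: 135         # resting-state epochs
epoch_duration: 0.5   # seconds
sampling_rate: 1000.0 # Hz
n_evoked: 49          # epochs averaged into the evoked noise; the
                      # remaining 86 estimate the covariance

# --- activations ----------------------------------------------------------
amplitude: 1.0e-8     # dipole moment per source, A*m (10 nAm)
activation_duration: 0.1   # seconds (100 ms)

# --- sweep ----------------------------------------------------------------
snr_grid: [0, 0.01, 0.1, 1, 3, 10, inf]
methods: [MNE, dSPM, sLORETA, eLORETA, MxNE]
n_virtual_subjects: 3
base_seed: 0

# --- MxNE solver ----------------------------------------------------------
mxne:
  alpha_pct: 55       # regularization as % of alpha_max (0 = none, 100 = all-zero)
  tol: 1.0e-6
  max_iter: 3000
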