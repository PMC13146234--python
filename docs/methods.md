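# Methods

## The estimation problem

A passive Wi-Fi packet sensor near an outdoor smoking area records probe
requests — short management frames phones broadcast while scanning — as
anonymized detections: timestamp, salted one-way hash of the MAC address,
vendor prefix (OUI), and received signal strength (RSSI, dBm). The quantity
of interest is *exposure opportunity*: how many smokers and how many
passersby are present per day within a radius (default 25 m) where
secondhand smoke is plausibly encountered. Devices are not people: not
everyone carries a phone, phones probe intermittently, and one person can
be missed or detected many times. The pipeline therefore converts
detections to *presence episodes*, classifies episodes by signal strength,
and scales classified device counts to person counts with capture ratios
measured against a brief manual observation.

## Pipeline stages

1. **Ingest.** Rows with an unparseable or offset-free timestamp, RSSI
   outside [−100, 0] dBm, a malformed OUI, or a non-hex device id are
   counted and dropped, never fatal. Identifiers are salted SHA-256 digests
   truncated to 16 hex characters; at site scale (≲10⁵ devices/day) the
   collision probability is negligible and no MAC bytes are recoverable.
   All clock arithmetic uses the site's local offset (+09:00).
2. **Business hours.** Detections outside the operating window (default
   10:00–22:00, half-open `[10,22)`) are removed. The half-open convention
   makes the boundary decision unambiguous; the effect is a handful of
   detections.
3. **Fixed-device exclusion.** Any OUI observed transmitting outside
   business hours is treated as fixed infrastructure and *all* records with
   that OUI are excluded. The rule is deliberately at OUI granularity: a
   human device sharing a vendor prefix with an access point is collateral
   damage the simulator can measure but the rule does not prevent. The rule
   also flags human devices genuinely probing out of hours (e.g. a visitor
   leaving after closing); that is the rule working as specified, not a
   defect.
4. **Episodes.** Per device, consecutive detections with gaps of at most
   `gap_threshold_s` (default 600 s) form one episode; larger gaps split.
   Episodes need ≥ 2 detections — a single detection has no dwell. The
   600 s default sits well above the mean inter-burst interval (~30 s) and
   well below plausible same-day revisits; it is a config field covered by
   the sensitivity grid.
5. **Dwell screen.** Episodes with dwell ≤ 6 min (inclusive) are eligible;
   longer episodes are likelier loiterers, workers, or parked devices.
6. **Classification.** The mean RSSI over an episode's member detections is
   mapped to a class by inclusive bands: [−75, −46] dBm → likely smoker,
   [−88, −76] dBm → likely passerby, anything else unclassified (and
   excluded from calibration and estimation). The mean is used because
   per-detection shadowing fluctuates by several dB while the behaviour
   does not; applying the bands per detection is the main alternative and
   is deliberately not done. Band disjointness is validated at config load
   and re-checked for every perturbed grid point.
7. **Calibration and estimation.** During the validation window (default
   15:00–15:30) manual per-class person counts and concurrently classified
   device counts (episode *start* inside the window) give per-class capture
   ratios (devices/person) and device-to-person multipliers
   (persons/device). Multipliers are rounded to one decimal *before*
   scaling and person totals to the nearest integer *after* — the order
   matters for reproducibility of reported totals and is fixed as a
   convention. Hourly profiles allocate the day total proportionally to
   hourly device counts, so rounding is applied once at day level.
8. **Sensitivity.** A grid of multiplicative perturbations (default ±10 %,
   ±20 %) on the dwell screen and all four band edges re-runs screen →
   classify → calibrate → estimate per point. Points with overlapping bands
   or undefined calibration are flagged invalid in the output table rather
   than dropped.
9. **Exploratory classifier.** A small random forest (10 trees, depth 5,
   min split 2) over dwell, mean RSSI, and RSSI variability (sample SD)
   separates smoker from nonsmoker stays, evaluated on a stratified
   hold-out (default 40 %) with stratified CV on the training part.
   Confusion-matrix metrics, class-weighted averages, and the rank-sum AUC
   are computed in-package; undefined class-conditional metrics are
   reported as null, never zero. The evaluation demonstrates metric
   arithmetic and feature separability on simulated stays; it is not a
   transportable classifier.

## The simulator

The generator emulates an outdoor smoking area beside a pedestrian
corridor, with the sensor at the origin:

- **Arrivals** are Poisson with piecewise-constant hourly rates. Defaults:
  bimodal smoker arrivals (noon and 16:00 peaks, ≈262/day) and
  noon-peaked passerby traffic (>500/h from 11:00 to 16:00, ≈3.9k/day)
  during 10:00–22:00 operation.
- **Smokers** hold an anchor point in a 1.5 m dwell zone around the
  smoking-area centre (4 m from the sensor) for a log-normal stay (median
  6 min, shape 0.6 — smoking-room stays are typically several minutes).
- **Passersby** cross a 30 m corridor 14 m from the sensor at 1.2 m/s, so
  each is present ~25 s.
- **Device carriage** is Bernoulli per person: 0.5 for smokers and 0.135
  for passersby. The low passerby default encodes a child-heavy crowd in
  which many people carry no phone; there is no explicit age structure.
- **Probe emission** is bursty: exponential inter-burst gaps (mean 30 s),
  1–4 probes per burst, giving ~10–40 detections over a 6-min stay.
- **Radio propagation** is log-distance path loss,
  RSSI = P₀ − 10·n·log₁₀(d/d₀) + ε, with P₀ = −40 dBm at d₀ = 1 m,
  exponent n = 3.5, and Gaussian shadowing ε (SD 4 dB). These are generic
  urban-propagation values chosen so that the two behavioural classes land
  inside the two classification bands (smokers at 2.5–5.5 m ≈ −54…−66 dBm;
  corridor crossings at 14–20 m ≈ −80…−86 dBm); no on-site RSSI–distance
  fit exists to calibrate against. Geometry is collapsed to 2-D horizontal
  distance, since at ≥2 m the 2.4 m sensor height contributes little.
- **Fixed devices** (default three, with vendor prefixes disjoint from the
  simulated-phone pool) emit around the clock from fixed positions.

Randomness uses one seed per scenario with deterministically spawned
sub-streams per person, so identical (config, seed) pairs give
byte-identical logs.

What the simulator does *not* emulate: MAC randomization churn within a
stay, multipath and body-shadowing structure, weather, correlated group
arrivals, or device-model differences in probe cadence. Passing tests
therefore show that the pipeline's logic and arithmetic are correct under
the stated statistical assumptions, not that real deployments achieve any
particular accuracy.

## Numerical conventions and degenerate inputs

- Percentages are rounded half-up to one decimal; person totals half-up to
  integers; multipliers half-up to one decimal.
- Episode membership in the validation window is by start time, half-open.
- Calibration with zero manual persons or zero classified devices raises a
  class-named error; sensitivity grid points inheriting that condition are
  flagged, not dropped.
- Empty logs, empty episode tables, and zero-rate scenarios flow through
  every stage and produce empty-but-well-formed outputs.
- The rank-sum AUC assigns tied score pairs one half.

## Test and validation problem sizes

Distributional tests run on scaled-down days (10–80 smokers/h,
80–400 passersby/h, ~10³–10⁴ detections), which keeps the full suite under
a minute while leaving ≥ 30 episodes per class for recall and separation
checks. The calibrated-recovery check uses five fixed seeds on a
well-powered scenario (≥ 100 true persons per class, ≥ 800/day) and
compares the mean estimate across seeds to the mean truth within ±25 %: a
single 30-min window yields only tens of classified devices per class, so
per-seed ratio estimates carry ~20 % sampling noise plus two small known
positive biases (window-overlap inflation of the manual count, ≈ stay
length / window length, and the convexity bias of the persons/devices
ratio estimator). This mirrors the method's real limitation: one brief
calibration window makes day-level totals provisional.

## Known limitations

- Capture ratios from a single 30-min window are noisy and time-varying in
  reality; no uncertainty intervals are produced (point estimates only; a
  bootstrap is a natural extension hook).
- The band rule's accuracy depends entirely on site geometry; the defaults
  here are not transferable.
- OUI-level fixed-device exclusion can remove human devices (shared vendor
  prefixes, out-of-hours visitors).
- Person counts are exposure opportunity, not dose: no pollutant
  concentrations are modelled.
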