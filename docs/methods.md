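# Methods

## Data model

The atom is one pump event-log record: `(pump_id, pump_model, timestamp,
event_kind, alarm_type, profile_text, drug_text, in_library)`. Event kinds
are `INFUSION_START`, `ALARM`, `RESTART`, `INFUSION_STOP`; alarm types are
the twelve states mined from syringe and large-volume pumps (flow error,
two air-in-line states, callback, door open, drive engage failure, end /
near-end of infusion, downstream / upstream occlusion, syringe disengaged,
end of syringe). `alarm_type` is present exactly when the kind is `ALARM`.

Timestamps are seconds since a fixed epoch on a 0.25 s grid — the
granularity at which the published reaction-time statistics are printed
(e.g. 444.25, 24.75) — and are serialised as ISO-8601 UTC strings with
millisecond precision, which round-trips the quarter-second grid exactly.
One `pump_id` is one logical channel; multi-channel devices are modelled as
distinct pump ids, since the source logs never distinguish channels.

## Normalisation

Drug-library profiles and drug entries are free text, so grouping is a
normalisation step, not a join. Matching is case-folded substring matching
against configurable stem lists (YAML), longest stem first; every input maps
to exactly one group, with `UNMAPPED` / `OTHER` as the totalising defaults,
so arbitrary Unicode never raises. The NICU synonym list is the published
one (neonatal variants, ICN, SCBU, SCN); the PICU/GICU/CICU lists are
supplied by this package because no authoritative synonym table exists for
them — extend them per site via `load_maps(path)` rather than editing code.
Text matching stems of two different drugs at equal maximal length falls to
`OTHER` with a warning; nested stems (adrenaline inside noradrenaline)
resolve longest-first. Glyceryl trinitrate (GTN/NTG) is intentionally not a
CSHL stem: its use does not extend across all critical-care areas, and it is
excluded from the drug group. Plasma half-lives (seconds): adrenaline
180, dobutamine 120, dopamine 60–120, noradrenaline 120–180.

## Episode reconstruction

A linear scan per pump: `INFUSION_START` opens an episode, `ALARM` attaches
to the open episode as an unresolved interruption, `RESTART` resolves every
alarm currently pending on that pump (assigning its timestamp as the restart
time), `INFUSION_STOP` closes. Orphan events — alarms, restarts or stops
with no open episode, restarts with nothing pending, and starts arriving
while an episode is open (the stale episode is closed open-ended) — go to a
rejects report with a reason, never silently dropped; every `ALARM` event is
accounted for either as an attached reaction or as a reject. Alarms never
resolved before episode end carry no reaction time and are excluded from
summary statistics, which cover resolved restarts only.

Repeat handling: reaction-time statistics use *first-time* alarms only. The
default rule flags an alarm as a repeat when an earlier same-type alarm on
the episode lies within the repeat window before it; the window defaults to
**120 s**, chosen to span the studied drugs' half-lives (60–180 s), and is
configurable because the underlying exclusion in the source protocol was a
manual review with no stated rule. A stricter variant
(`rule="restart"`: an alarm is a repeat only when it re-announces a
condition not yet followed by a restart) is provided behind the same switch.

## Derived metrics and rounding

All table-style values are rounded **half-up to 2 decimals**, computed with
exact decimal arithmetic from integer counts (the only rounding rule
consistent with every verifiable printed cell). Percent-style quotes keep
their quoted precision (integer for the near-end-of-infusion share of
starts, 1 dp for the end-of-infusion + end-of-syringe share of CSHL starts).

The critical-care "alarms per infusion" aggregate is the **unweighted mean
of the four per-area ratios** (3.71, 4.36, 1.33, 8.61 → 4.50), not the
pooled quotient of summed counts (≈ 2.49); both are computed and reported
side by side under distinct names, because only the former reproduces the
published aggregate. Reaction-summary SD is the population SD (n
denominator) by default — the source does not state n vs n−1 and its raw
inputs are unpublished either way — with `ddof` configurable.

Absent (printed N/A) cells — e.g. air-in-line counts in syringe-pump-only
areas — are represented as *absent*, and absence is preserved through every
aggregation; absent ≠ 0.

Three published derived values do not follow from the published raw counts
and are pinned as known mismatches in `KNOWN_PRINT_DISCREPANCIES` (printed
vs recomputed): critical-care total alarms 467,437 vs 467,237 (both the sum
over the four areas and the sum over the twelve alarm types give 467,237);
whole-population alarms per infusion 1.39 vs 1.38; whole-population
downstream-occlusion-to-start ratio 0.52 vs 0.53. The published
critical-care occlusion-to-start ratio 1.38 is reproducible neither as the
pooled quotient (0.73) nor as the mean of area ratios (1.51) and is treated
as non-reproducible. Tests assert the mismatches so neither side gets
silently "fixed".

Half-life exceedance classifies a reaction time against the drug's maximum
half-life: within one half-life, exceeding it, or **extreme** beyond six
half-lives (the published marker for clinically unacceptable outliers,
≈ 13 min for the drugs concerned).

## Synthetic log generator

The raw study logs (~1,183 pumps) are not available, so the simulator
emulates their statistical structure, with defaults taken directly from the
embedded count tables — the defaults *are* the study conditions, not tuning
knobs:

- **Care-area mix and rates.** The default configuration is the NICU column:
  non-CSHL alarm mix and rate are the NICU counts minus the four-drug CSHL
  counts (≈ 4.05 alarms per non-CSHL infusion); CSHL infusions occur at the
  observed fraction of starts (3,623 / 30,527 ≈ 11.87 %), with the observed
  drug mix and the four-drug alarm mix (≈ 1.23 alarms per CSHL start, 73.8 %
  of them callbacks). The blended rate reproduces ≈ 3.71 alarms per
  infusion.
- **Reaction times** are i.i.d. contaminated lognormal: lognormal(μ = 2.86,
  σ = 0.9) in log-seconds (median exp(μ) ≈ 17.5 s, matching the published
  NICU median), multiplied by 10 with probability 0.02 to produce the
  observed extreme outliers (maximum ≈ 25× the median), clamped to ≥ 0.25 s
  and quantized to 0.25 s. No serial-correlation structure is modelled; the
  source gives none.
- **Repeats.** Each alarm is re-raised once, same type, shortly after its
  restart with probability `p_repeat` (default 0.05), so the first-time
  filter has true positives. Primary alarms are drawn at rate
  target/(1 + p_repeat), making the *logged* alarm rate equal the configured
  target, as a log tally would count it.
- **Free text.** Profiles are sampled from the published NICU name variants
  ("NEONATOLOGIE", "SCBU", "NICU rule of 6", …) and drugs from realistic
  concentration-bearing variants ("Noradrenaline 4mg/50ml",
  "norepinephrine"), exercising the normalisation layer end to end.
  Non-CSHL infusions start from the drug library at the observed 67.39 %
  rate; non-library starts carry no drug text.
- **Determinism.** Each pump derives an independent substream from the
  global seed (`default_rng([seed, area_index, pump_index])`); the same seed
  yields a byte-identical event stream regardless of generation order.
- **Ground truth.** The generator records every count, repeat flag and true
  reaction time, so pipeline output is compared against what was generated
  (exact equality for counts), not against another estimator.
- **Occlusion sub-model.** Line pressure ramps linearly from baseline at a
  constant rate (mmHg/s); a fixed threshold alarms after
  (threshold − baseline)/rate, a dynamic auto-offset threshold (default
  30 mmHg above line pressure, the recommended setting) after offset/rate.
  Dynamic never alarms later than fixed whenever baseline + offset ≤
  threshold.

What the simulator does **not** emulate: clinician workload, geography and
shift structure (reaction times are exchangeable draws, not queue
outcomes); per-device clock drift and the device-default date artefacts of
real CQI exports; hardware recovery behaviours (Fast Start, Back Off)
beyond their net effect on reaction/resolution times; and cross-pump
correlation of alarms. Passing parameter-recovery tests therefore shows the
*pipeline* is unbiased on logs with the assumed structure — it does not
validate the distributional assumptions against real wards.

## Test and acceptance problem sizes

Episode reconstruction is checked for exact agreement against an O(n²)
brute-force matcher on structureless random logs (10,000 events, orphans and
mid-episode starts included). Summary statistics are checked against an
independent two-pass computation on 5,000 simulated reactions. Parameter
recovery runs 10,000 simulated infusions (≈ 95,000 events, a few seconds):
alarms per infusion within 5 %, per-type mix within 2 percentage points,
reaction mean within 5 %, CSHL callback share within 3 points of the
configured 90.48 per 100 starts. Recovery identities and the
fixed-vs-dynamic threshold monotonicity are checked on 1,000 randomized
scenarios. `scripts/acceptance.py` re-derives the fixture quantities and
re-runs the 10,000-infusion recovery from a fresh seed.

## Known limitations

- Non-NICU care-area synonym lists and the per-alarm priority assignment
  (priority → beacon/tone pairing is published; the per-alarm mapping is
  not) are package-supplied conventions.
- The published reaction-time table (means/SDs per area) is not
  reproducible from any available data and is deliberately not asserted;
  the simulator targets its shape (median, outlier prevalence), not its
  exact moments.
- Multi-channel pumps sharing a physical id would need channel-suffixed
  pump ids upstream of this package.
- The repeat-window rule can misclassify two genuine same-type alarms
  landing within the window; with the default parameters this affects a
  negligible fraction of alarms and is the price of a deterministic rule.
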