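# Methods

## Coordinate and classification conventions

All positions are relative to the first base of the annotated CDS, 1-based
with no position 0 (CDS first base +1, last transcript-leader base −1).
This matches the convention of published uORF/oORF location tables in which
the start column is the uAUG first base and the stop column the third base
of the stop codon. One consequence worth stating explicitly: a nucleotide
span that straddles the leader/CDS boundary is `stop − start` nucleotides
long, not `stop − start + 1`, because position 0 does not exist. The span
identity used in validation is therefore

    stop_third_base − start + 1 − [start < 0 < stop] = 3 × (length_aa + 1)

`length_aa` counts sense codons including the initiator Met and excluding
the stop; a "6 amino acid" oORF occupies a 21-nt span with its stop.

A uAUG must lie wholly within the leader (start ≤ −3): an AUG straddling
the boundary is not an upstream initiation event. Each uAUG is scanned
independently; nested and overlapping ORFs are all reported, and two uAUGs
in one frame may share a stop codon (as in the human STN1 leader). Walking
3'-wards in steps of 3, the first TAA/TAG/TGA decides the class:

| class | condition |
|---|---|
| uORF | stop's third base ≤ −1 (stop wholly inside the leader); any frame |
| oORF | frame offset ≠ 0 and stop's third base ≥ +1 (including +1, the shared-stop boundary case) |
| n_terminal_extension | frame offset 0 and no stop wholly within the leader |
| no_stop_in_window | frame offset ≠ 0 and no stop within leader + window |

The frame offset is `(distance from uAUG to CDS first base) mod 3`. uORFs
can occur in 3 reading frames and oORFs in exactly 2 — an in-frame upstream
AUG that stays open is an extension of the main protein, never an oORF.
N-terminal extension calls carry no stop coordinate: their only in-frame
stops lie in the CDS frame downstream and recording one would make the call
depend on the arbitrary window size. Codons containing N match neither ATG
nor stops; genes whose leader contains N are flagged in their summary.
`no_stop_in_window` calls (vanishingly rare at the default 300-nt window)
are reported but excluded from all cohort fractions.

The downstream window default is 300 nt of CDS-side sequence, enough to
contain the first out-of-frame stop at any realistic base composition; it
is configurable everywhere.

## Permutation null

The expected frequency of uORFs/oORFs absent selection is estimated by
individually shuffling each leader — a uniform random permutation of its
own bases, preserving length and mononucleotide composition — and
rescanning against the gene's *real* downstream sequence, so oORF stop
search runs into genuine CDS. The default is a single randomization per
leader (the classical design for this comparison); the documentation and
`ExpectedFractions` support ≥ 10 replicates with mean ± sd, which we
recommend for stable estimates. No dinucleotide-preserving shuffle is
offered by default: the null is defined as composition-matched random
sequence.

## Exact occurrence model

For an i.i.d. leader of length L with base probabilities π, the probability
that it contains ≥ 1 uORF, ≥ 1 oORF, or ≥ 1 open in-frame uAUG is computed
exactly by a dynamic program over a product automaton. The leader is read
base by base; for each of the three codon phases the automaton tracks the
informative prefix of the pending codon (enough to recognize ATG, TAA, TAG,
TGA on completion: one of "", A, T, other, AT, TA, TG, other-2) and whether
an ORF opened in that phase is still open; one global bit records whether
any ORF has been closed by a stop wholly inside the leader (⇒ uORF
present). At the end, an open phase whose frame offset is nonzero implies
an oORF — the CDS region is modeled as providing an in-frame stop with
probability 1, and the class is oORF whether that stop straddles the
boundary or not — while an open in-frame phase implies an extension. The
joint state space stays under ~1000 states, so the computation is exact and
linear in L.

The permutation null conditions on each leader's realized composition; the
analytic model assumes i.i.d. draws. Per gene the two differ (a permutation
of one observed leader is not an i.i.d. draw), but over cohorts generated
i.i.d. they agree in expectation, which is what the calibration tests
check. Two closed-form anchors: at uniform composition
p_uORF(6) = 3/4096 (the leader must be ATG + one of three stops) and
p_oORF(4) = 1/64 (ATG at the 5' end, frame 1, open at the boundary). The
brute-force oracle (`enumerate_presence_prob`) sums the probability mass of
every 4^L leader whose scan contains the class and agrees with the DP to
< 1e−12 for L ≤ 8 under uniform and AT-rich compositions.

## Selection statistics

Cohort fractions are the share of genes with ≥ 1 uORF and ≥ 1 oORF (a gene
with both counts in both). Length stratification uses 25-nt bins by
default (no canonical binning exists; it is a parameter), flagging bins
with < 20 genes as low-support. The O/E curve divides observed by expected
fractions per bin (NA when expected is 0) and reports a qualitative flag:
whether the oORF ratio lies below the uORF ratio in every supported bin
beyond 50 nt, the signature of stronger selection against oORFs in longer
leaders.

The abundance contrast compares uORF-only against oORF-only genes (genes
with both or neither are excluded from the test only, not from fractions)
with a two-sided unpaired t-test — Student's pooled-variance by default,
with Welch and log10-transform options. Box statistics follow the Tukey
convention: quartiles by linear interpolation between order statistics,
whiskers at the most extreme data points within 1.5 × IQR of the nearer
quartile. (A literal "largest data point less than 1.5 × IQR" rule would
compare data to a scale-free scalar and is meaningless on abundance
scales; the Tukey fence is the standard reading.)

## Variant re-annotation

Substitutions are specified in relative coordinates (`-13A>T`); edits at
≥ +1 are allowed but flagged since they alter the CDS. Multiple
substitutions are applied in one pass, 5' to 3'. Architecture diffs match
calls by start coordinate — a stop mutation preserves the start, a start
mutation destroys the call — and tag events as start_loss,
stop_loss_extension, stop_gain_truncation and class_change (e.g. a uORF
whose stop moves past the boundary becomes an oORF). Because every uAUG is
reported independently, destroying one start can never create calls;
exhaustive small-leader enumeration verifies this.

## Synthetic data

The generator emulates the *shape* of real TL cohorts, not their full
statistics: lengths from a lognormal parameterized by its median (presets:
yeast-like 49 nt, human-like 173 nt; only medians are reported for the real
cohorts, so the spread σ = 0.6 on the log scale was fixed once as a
realistic value), bases i.i.d. from a configurable composition, and
downstream sequences that begin with ATG and carry an in-frame CDS stop
within the window. It does not mimic promoter composition gradients,
dinucleotide structure, codon usage or isoform heterogeneity — so passing
tests demonstrate correctness of the machinery, not biological realism of
any particular number.

Planted mode draws per-gene uORF/oORF presence as independent Bernoullis
with the requested prevalences, scrubs all accidental uAUGs from the
background, writes the planted architecture at randomized coordinates, and
derives the truth call (start, stop, class, length) with its own coordinate
arithmetic, independent of the scanner. Because random context can corrupt
a plant (e.g. create an extra uAUG spanning a junction), every gene is
verified by re-scan and regenerated on mismatch, with a bounded retry count
(default 50; exceeding it raises with the colliding parameters). Depleted
mode rejection-samples leaders that contain an oORF with a configurable
probability, creating a known negative-selection signal while leaving
composition and lengths otherwise natural. Synthetic abundances are
log-normal (log10 mean 2.5, sd 0.6 — a proteome-like ppm scale) with a
planted decrement for oORF-only genes (default 0.5 log10; the real effect
size is not pinned down, only its direction).

The STN1-style fixtures are deterministic sequences, labelled synthetic:
real STN1 leaders are not bundled (see `leaderscan.realdata` for how to
supply them). The yeast fixture places the 16-codon uORF start 78 nt
upstream of the CDS and gives the 6-codon oORF a stop at +2..+4. A note on
that geometry: a stop whose third base is at +2 is impossible when the CDS
begins ATG (the stop would have to end in "AT"), so "terminating 2 bases
after the CDS start codon" is realized as the terminator *beginning* 2 nt
into a CDS that starts ATGA — the same boundary geometry the classifier
examples use. The oORF start then falls 17 nt upstream. The published
coordinate set (start 13 nt upstream, 6 codons, terminating 2 bases in) is
internally inconsistent under any single counting convention, so the
fixture fixes the lengths and class boundaries and treats offsets as
parameters. The human fixture realizes two overlapping oORFs of 15 and 19
sense codons sharing a TAA whose third base is the first CDS base.

## Numerical and testing choices

* Probability vectors must sum to 1 within 1e−12; DP-vs-oracle agreement is
  asserted at 1e−12 absolute.
* Calibration tests use 3-binomial-SE bands on fractions and O/E ratios;
  the t-test's type-I error is checked at 0.05 ± 0.01 over 5000 simulated
  null cohorts (30 per group).
* Problem sizes in the test suite — 2000 genes for no-selection
  calibration, 600 for planted recovery, 1700 for the abundance power check
  (≥ 200 genes per group at δ = 1 log10, α = 0.001), exhaustive
  enumerations at leader lengths 6 and 9 — were chosen as the smallest
  cohorts at which the checked statistical properties are unambiguous.
* Shuffling asserts composition preservation on every replicate; cohort
  statistics are invariant to record order.

## Known limitations

* Only AUG starts are considered (no CUG/GUG near-cognates), no start-
  context (Kozak) scoring, and no ribosome-profiling evidence integration.
* The analytic model and generator treat bases as i.i.d.; real leaders have
  local composition structure that the permutation null (per-gene,
  composition-exact) handles but the analytic curves do not.
* No isoform quantification: one leader per gene, with TL lengths supplied
  by the user ("longest isoform" upstream choices are the caller's).
* Genome-scale observed/expected percentages and the real STN1
  architectures depend on user-supplied annotation; the package ships only
  generators and fixtures.
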