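# Methods

## The amplification model

`nemabar` treats PCR amplification as a binary, per-template event governed
by primer-template matching alone. A primer of length *L* placed at offset
*i* on an ungapped template yields a per-position mismatch vector
m ∈ {0,1}ᴸ, where position *j* is a mismatch unless the IUPAC expansion sets
of the primer base and the template base intersect. The placement is
accepted when

- Σ m ≤ `max_mismatches` (default **2**), and
- the mismatches within the last `three_prime_window` nt (default **3**) of
  the primer's 3′ end number at most `max_three_prime_mismatches`
  (default **0**).

The strict 3′ rule is the whole specificity mechanism: a mismatch at or
near the 3′ terminus prevents polymerase extension, which is the documented
basis for the NemF primer discriminating nematode (and other metazoan) SSU
templates from fungal and plant ones, whose sequences diverge from NemF at
positions 5, 14 and 19 — position 19 being the 3′-terminal base. The body
tolerance of 2 stands in for the permissiveness of a moderate annealing
temperature. There is **no thermodynamic model**: annealing temperatures,
cycle numbers and amplification efficiency are not represented, so two PCR
rounds with different stringencies can only be expressed as different
`MatchParams` per round. Template `N` residues are governed by an explicit
policy (`permissive-match` by default; `count-as-mismatch` treats them as
mismatching every primer base); all other degenerate template letters match
by set intersection.

A primer pair amplifies when a forward site and a downstream reverse-primer
site (matched as the reverse complement on the plus strand) bound a product
of length within `[min_product, max_product]` (default **[100, 2000]** nt —
wide enough for SSU-scale inserts, narrow enough to exclude degenerate
pairings). All valid (forward, reverse) pairings are reported; composition
summaries count templates, not products, to avoid double-counting. Reference
sets are assumed orientation-normalized, so forward primers are scanned on
the plus strand only.

The semi-nested strategy is two rounds: the outer pair (NemF/18Sr2b by
default) amplifies the template, then each outer product becomes the
template for the inner pair (NF1/18Sr2b), which must share the outer reverse
primer. Nested products are mapped back to original-template coordinates and
are, by construction, contained in their parent product.

Tag decoration reproduces the 454 library layout: the plus-strand tagged
product is `adapter_fwd + MID + insert + revcomp(adapter_rev)`. With the two
published 25-nt adapters and a 10-nt MID, tagging adds exactly 60 nt; the
default simulated insert of 350 nt therefore yields a 410-nt tagged product,
the scale of the sequenced amplicon. The shipped 22 MIDs are synthetic
stand-ins (pairwise Hamming distance ≥ 3, no homopolymer > 2 nt) because the
commercial MID sequences used in the original libraries are unpublished.

## Conservation profiles and consensus rows

Given an aligned reference set, the primer site is located by scanning each
record's ungapped sequence for its best acceptable placement (fewest
mismatches, ties to the leftmost start), mapping that placement's positions
to alignment columns, and taking the modal column run; records that place
the site elsewhere, or have none, are reported rather than dropped.

*Conservation* at a primer position is the percentage of the group's
sequences whose residue IUPAC-matches the **primer** base — not the
frequency of the modal base — rounded half-up to an integer. Gap residues
are excluded from both numerator and denominator: an indel carries no
evidence about base identity. Positions where every record is gapped report
no percentage at all rather than 0.

The consensus row takes, per position, the unique most frequent non-gap
residue when its frequency reaches `majority_threshold` (default 0.5); on a
tie at the top, or when no residue reaches the threshold, it falls back to
the minimal IUPAC code covering every residue at frequency ≥ 0.25 (so a
50/50 A/G split renders as R). The letter prints as `.` when it
IUPAC-matches the primer base. The in-group for the percentage row is
user-designated (default: phylum Nematoda); whether "Metazoan" excludes
Nematoda is left to how the user labels and subsets the reference set.

## The synthetic-data generator

Every simulated template follows one layout: 100-nt flank, NemF site (19
nt), 30-nt spacer, NF1 site (24 nt), 305-nt insert, reverse-complemented
18Sr2b site (21 nt), 100-nt flank — 599 nt in total, chosen so the nested
NF1→18Sr2b product is 350 nt and the tagged product 410 nt. Taxon
*signatures* place exact substitutions at chosen primer positions (the
shipped fungal/plant signature is 5→G, 14→C, 19→G on NemF); background
substitutions are applied independently per site at `background_sub_rate`
**outside** all primer sites, so primer-site identity is controlled solely
by signatures and the specificity mechanism stays separable from noise.
Flanks, spacer and insert are drawn once per configuration, so same-taxon
records differ only by background noise; all records share coordinates and
are emitted as a gap-free alignment the profiler can consume directly.

Read simulation draws source records with probability proportional to
abundance among records the nested strategy amplifies, emits full nested
amplicons, and applies independent per-base substitution errors. Defaults
for the study-scale conditions used in tests: a four-taxon community with
one 3′-blocked taxon, background substitution rate 0.005, per-base read
error 0.002, 10,000 reads.

What the generator does **not** emulate: real SSU sequence composition and
secondary structure, indels and alignment gaps from real divergence,
chimeras, homopolymer (flowgram) errors, quality scores, or amplification
efficiency bias. Passing tests therefore demonstrate the correctness of the
matching/exclusion machinery and the internal consistency of the pipeline,
not quantitative recovery on real soil communities.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only in rendered
  tables. Gaps `-` and `.` are both accepted and normalized to `-`; RNA `U`
  is normalized to `T`; case is folded to upper.
- Percentages round half-up (81.5 → 82) to match integer table display.
- Site lists sort by (mismatch count, start); "best site" ties break to the
  leftmost start, making every result deterministic.
- Canonical ranks are kingdom…species; extra lineage fields are dropped with
  a warning; records with no lineage get an `Unclassified` kingdom.
- All randomness (generator, read simulator, CLI) flows through seeded
  `random.Random` instances; fixed seed ⇒ byte-identical outputs, which the
  run manifests (SHA-256 digests of inputs and outputs) make checkable.
- Empty results are not errors (no sites on a too-short template, an
  unamplifiable community profile); genuinely contradictory configuration is
  (inner/outer reverse primers differing, MID ≠ 10 nt, signature positions
  outside the primer).

## Known limitations

Binary amplification ignores efficiency, so abundance distortion by primer
bias cannot be studied here. The 3′-window rule is a proxy, not a kinetic
model; its defaults are package decisions exposed as flags, since no numeric
mismatch tolerance is published for the original in-silico prediction. The
profiler requires an aligned input; it does not build alignments.
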