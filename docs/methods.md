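# Methods

This note documents the models, rules and numerical choices behind
`faers_forge`, in the spirit of a statistical package's methods appendix.

## Data model

The unit of analysis is the *case report*: one row in the combined DEMO
table, keyed by `primaryid` (the legacy extracts' `ISR` values are used
verbatim as `primaryid`; a `source` flag records the originating system,
and a `period` field records the quarter each row came from). Every report
carries at least one drug mention and one adverse-reaction preferred term;
indications, therapy dates, outcomes and report sources are optional
satellites keyed by `primaryid` (and drug sequence number where relevant).

Parsing is deliberately conservative: files are split on the literal `$`
delimiter with no quoting dialect (the extract layout), a row with the
wrong field count is quarantined with its line number, and parsed +
quarantined rows always reconcile with the physical line count. Dates are
kept as 8-digit `YYYYMMDD` strings; partial dates (`YYYY`, `YYYYMM`) are
preserved as-is and compared only by exact string equality downstream —
prefix-matching partial dates would silently over-merge duplicates.

Ages are normalized to years with conventional calendar factors
(decade ×10, month ÷12, week ÷52, day ÷365, hour ÷8760), centralized in
one table. Values outside a plausible 0–150-year range, unknown units and
non-numeric input become null rather than poisoning the duplicate-matching
age criterion. Reporter countries normalize through a bundled
case-insensitive alias table to ISO 3166 alpha-2; unmatched raw values are
tallied in the audit log and become null.

## Deduplication

Stage 1 keeps one report per case identifier: maximum `caseversion`, ties
broken by latest `fda_dt`, then numerically largest `primaryid`. Rows with
no case identifier pass through. Deleted-case lists (present in extracts
from 2019Q1) are applied next; removal is idempotent.

Stage 2 targets the same real-world case reported under different case
identifiers. Two reports are duplicates when

* the *hard keys* match exactly: the set of administered drugs and the set
  of adverse-reaction terms, and
* at most one of six *soft keys* mismatches: gender, age (whole years),
  reporting country, event date, the set of distinct therapy start dates,
  and the set of indication terms.

Null handling is the genuinely open design point: a soft key that is null
on either side is treated as a non-consuming *unknown* — it neither
matches nor spends the single allowed mismatch. The rationale is that
missingness degrades a criterion's discriminating power; making a null
count as a mismatch would mean a 46%-null field (event date) vetoes most
true duplicates, while making it a match is equivalent in decisions but
misleading in reports. The policy is configurable
(`null_policy = unknown | match | mismatch`).

Drugs are compared at standardized single-ingredient level (mapping runs
before cross-dedup), so "ASPIRIN" and "aspirin 81mg" mentions match. Rows
the mapping cascade could not resolve contribute their deep-cleaned
verbatim string as a tagged stand-in key — a case with one unresolvable
(e.g. misspelled) drug can still be matched to its duplicate, which is
required for exact duplicate recovery; a case is excluded from stage 2
only when it has no drug or no reaction rows at all. A `verbatim`
comparison level is available as a switch.

Candidate pairs are blocked on the exact (drug-set, reaction-set) pair.
Because the rule requires exact hard-key equality, blocking is provably
lossless (asserted against an exhaustive pairwise oracle in the tests).
The pairwise relation is not transitive, so pair edges are closed with
union-find into disjoint groups; within a group the report with the latest
`fda_dt` (then largest `primaryid`) is retained.

## Drug-name standardization

Resolution is exact-lookup only — no fuzzy matching — so every mapping is
reproducible and auditable. The cascade order is: NDA number, exact match
after minimal cleaning, trade-name dictionary (IDD), manual overrides,
exact match after deep cleaning, trade-name dictionary on the deep-cleaned
string. The first hit wins and its stage is recorded as the row's single
provenance tag (`NDA`, `EXACT`, `IDD`, `MANUAL`, `CLEANED_EXACT`,
`CLEANED_IDD`, `UNMAPPED`).

*Minimal* cleaning: whitespace collapse, uppercasing, removal of embedded
reporter codes (`/01483701/`-style), stray `?`, unmatched brackets and
leading/trailing separator characters. *Deep* cleaning additionally
removes `^MANUFACTURER^` tags, echoed parentheses (`X (X)` → `X`),
strength+unit tokens (`4MG`, `0.5 ML`, `100 IU`, …) and dosage-form tokens
from a bundled stop list (`TABLETS`, `SUPPOSITORIES`, `I.V.`, …). Both
levels are applied to a fixed point and are idempotent (property-tested).
The exact symbol set is assembled from the messy-name styles observed in
the extracts and is config-extensible.

Matched atoms are normalized to single-active-ingredient level by a
bounded breadth-first walk (default 5 hops, cycle-guarded) over the
vocabulary's `has_ingredient` / `consists_of` / `tradename_of` /
`form_of` / `has_precise_ingredient` relations. Multi-ingredient products
yield one row per constituent, all sharing the parent `drug_id`, so
combination products remain traceable and ingredient-level counts are
correct. Exceptions: vaccine atoms are kept whole (`vaccine` flag), atoms
whose non-primary-source form is deliberately more granular keep that form
(`granularity`), and ingredients maintained only outside the primary
source vocabulary are flagged `non_rxnorm_ingredient`. A failed walk
fails closed to `UNMAPPED`.

Ambiguous names (one string, several atoms) prefer primary-source
ingredient-level atoms, then any ingredient atom, then primary-source
atoms, then the lowest atom id — a deterministic tie-break. The post-2014
`prod_ai` field is used only as a validator: disagreements with the
verbatim-name mapping are counted and reported, never allowed to override
it. Frequent unmapped names (default threshold 200) are surfaced in the
mapping report as candidates for the manual override table; the package
ships no fabricated curations.

## Contingency table and statistics

Counting is at the level of distinct reports: a case mentioning the same
(ingredient, event) pair repeatedly contributes once. For pair (X, Y):
`a` = reports with X and Y, `a+b` = reports with Y, `a+c` = reports with
X, and N is the total number of deduplicated reports (passed explicitly so
reports with no mapped drug still count toward the universe); `d` is
derived. N is identical across all cells of one table.

Statistics per cell (z = 1.96 for all intervals, natural log for the
ratio CIs, base-2 log for the IC, exactly as conventionally printed):

* PRR = [a/(a+c)] / [b/(b+d)],
  CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+c) + 1/b − 1/(b+d)))
* ROR = ad/bc, CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))
* Yates χ² = N·(max(0, |ad−bc| − N/2))² / [(a+c)(a+b)(b+d)(c+d)]
* a_exp = (a+b)(a+c)/N, IC = log₂((a+0.5)/(a_exp+0.5)),
  IC025 = IC − 3.3(a+0.5)^−½ − 2(a+0.5)^−³ᐟ², IC975 = IC + 2.4(a+0.5)^−½ −
  0.5(a+0.5)^−³ᐟ²

Numerical policy decisions:

* **Zero cells.** Ratio statistics are undefined on zero cells and are
  returned null with a `zero-cell` reason code rather than silently
  Haldane-corrected; an opt-in `continuity` constant (e.g. 0.5) is
  available for users who want finite estimates. The IC is total for every
  a ≥ 0 because of its +0.5 shrinkage.
* **χ² clamp.** The classical Yates formula goes negative-inside-the-square
  when |ad−bc| < N/2, which would assign an exactly proportional table a
  spuriously positive statistic; the continuity term is clamped at zero, so
  proportional tables score exactly 0. Note that SciPy's implementation
  instead shifts observed toward expected by 0.5 and therefore differs on
  (and only on) cells with |ad−bc| < N/2; the two agree to ~1e-11 relative
  elsewhere (tested).
* Sign concordance (ad ≷ bc ⇔ ROR ≷ 1 ⇔ PRR ≷ 1 ⇔ IC ≷ 0) and interval
  containment hold by construction and are property-tested over randomized
  cells.

## Synthetic data generator

The generator emulates the documented statistical shape of the reporting
database at desk scale: marginal null rates (gender 11%, female share 54%,
US reporter share 65%, country 7%, event date 46%, age 40%, therapy start
date 42%, indication 12%), legacy vs current quarterly layouts, messy drug
strings from weighted corruption operators over a bundled ~50-ingredient
invented mini-vocabulary (brands, combination products, vaccines, foreign
trade names, NDA numbers), cross-source duplicates perturbed in at most
one soft field, deleted-case lists, and planted drug–event signals. Field
missingness is independent per field by default; the documented 32% joint
event/start-date missingness is available as an opt-in correlation knob.
Missing indications are emitted half as empty fields and half as the
unknown-indication placeholder phrase, both null-equivalent downstream.

Ground truth must be *exactly* recoverable, which needs two construction
guarantees. In general mode, the (drug-set, reaction-set) hard key is
unique per true case (rejection sampling over a combination space far
larger than any desk-scale n), so no two distinct cases can satisfy the
duplicate rule. In planted-signal mode many cases intentionally share hard
keys, so each true case instead gets a unique event date and a unique
therapy start date from disjoint calendar ranges (duplicate perturbations
draw from a third range): distinct cases then always differ in at least
two soft fields. Without one of these guarantees a zero-false-merge
expectation would be statistically incoherent — two genuinely
indistinguishable reports *should* merge under the rule.

Planted signals come in two forms. Exact cells (a, b, c, d) are realized
by construction — which requires a+b+c+d = n_cases, since d counts every
remaining case — and are recovered exactly through the full pipeline when
no duplicates are injected. A target reporting odds ratio is realized
stochastically (exposure probability 0.15, baseline event rate 0.08, the
exposed event rate solved from the target odds ratio), which is what makes
interval-coverage experiments meaningful.

What passing tests on this generator do *not* show about real data: real
FAERS missingness is correlated with era and reporter type, real duplicate
reports can differ in more than one soft field (recall there is bounded by
the rule itself, not by the implementation), verbatim names are far more
heterogeneous than six corruption operators, and the real vocabulary is
five orders of magnitude larger. The generator validates the *machinery*
(exact rule application, lossless blocking, cascade correctness, count
algebra), not epidemiological realism.

## Validation problem sizes

Chosen as realistic desk-scale cohorts: duplicate recovery at 10,000 cases
with duplicate rate 0.2; blocking-vs-exhaustive equivalence at 500 cases;
mapping recovery at 3,000 cases; planted-cell exactness at 1,000 cases;
interval coverage over 400 replicated end-to-end runs of 800 cases each
(at these cell sizes the Woolf interval's true coverage is ≈95.1%, so the
nominal band is the right yardstick); missingness at 10,000 cases against
a ±3 percentage-point band. The statistics oracle runs 10,000 random
cells at 1e-9 relative tolerance.

## Known limitations

* Exact-lookup mapping cannot resolve typos by design; they surface in the
  mapping report for manual curation instead (a similarity-suggestion mode
  would be a natural extension).
* The duplicate rule is the eight-criterion/one-mismatch rule throughout;
  probabilistic record linkage is out of scope.
* MedDRA terms are treated as opaque labels — no hierarchy expansion.
* Partial dates compare by string equality only.
* The pipeline is single-machine and deterministic; quarterly files are
  parsed into memory, which is fine for desk-scale and single-quarter work
  but a full two-decade run needs a chunked driver around the same stages.
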