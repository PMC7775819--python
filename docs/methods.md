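# Methods

## Study design implemented

The analysis is an intrasubject (paired) comparison.  For every user, drug
mentions that suggest actual intake ("intake-confirmed" mention events)
anchor treatment windows on the author's local calendar:

* **in-treatment**: any date `d` with `0 ≤ d − m ≤ 30` days for some
  intake-confirmed anchor `m`.  The anchor day itself is day 0 and counts as
  in-treatment — the intake tweet was posted while taking the drug.
* **unknown-treatment**: dates strictly more than 90 days from *every*
  mention (confirmed or not).  "More than 90" is strict: day 90 exactly is
  excluded; day 91 is unknown.
* **excluded**: everything else (the washout zone).

Two anchor sets are used because the design distinguishes *intake* mentions
(opening treatment windows) from *any* drug mention (blocking the unknown
period); both are configurable (`in_treatment_anchor`, `washout_anchor`).
Distances are computed on local calendar dates, not timestamps, so daylight
/ clock artifacts cannot move a tweet across a window boundary.  Users need
at least 30 tweets in both datasets to enter the analysis (inclusive
boundary); a threshold sweep over {10, 30, 60, 100} is reported with every
run.

Retweets are removed first: the flagged ones, plus (by default) any text
beginning with "RT @" after stripping leading whitespace, since old-style
manual retweets carry no flag.  Users with no retrievable UTC offset default
to UTC and are flagged in the rejects report rather than dropped.

## Feature battery

One vector per user × period, all clock-derived fields on the author's
local time:

| family | fields | convention |
|---|---|---|
| temporal | tweets_per_day, pct_daytime, tweets_per_weekday_day, tweets_per_weekend_day, pct_weekday | daytime = hours [8, 24); weekdays = Mon–Fri |
| length | mean_chars, mean_words | chars = Unicode codepoints of the raw text incl. spaces; words = tokens of kind word or number |
| links/mentions | pct_with_link, pct_with_mention | tweet-level indicators |
| POS | pos_verbs … pos_adjectives | % of POS-taggable word tokens, excluding conjunctions, interjections, punctuation, determiners, adpositions, numbers, dates; an `other` catch-all absorbs the remainder so the full composition sums to 100 |
| pronouns | pron_p1s … pron_p3p | % of personal pronouns; missing when a user-period has none |
| emotions | emo_happiness … emo_surprise | tweet-level indicator (≥1 lexicon word); a word-share variant is available behind `emotion_mode="word_share"` |
| negation / polarity | pct_negation, pct_positive, pct_negative | tweet-level indicators |

`tweets_per_day` divides by the distinct calendar days of the period's
windows clipped to the user's observed span (first to last tweet), so quiet
days count and partially observed windows do not inflate rates.  Emotion,
negation and polarity are indicators rather than word frequencies because
the design counts "tweets with one or more" category words; the word-share
alternative is kept behind a switch and labelled in the output manifest.

Zero denominators (no personal pronouns, no taggable words, no weekend days
in a window) yield missing values, which the paired stage handles by
complete-case analysis per feature.

## Tokenization and tagging

The tokenizer is a single-pass regex tokenizer aware of Twitter syntax:
URLs, @mentions and #hashtags stay single tokens with their own kind; words
keep Spanish accented characters; everything else degrades to
number/punct/other.  It drops nothing — filtering is a separate concern.

POS tagging is a *contract*: any object with `tag(tokens, kinds) →
TaggedToken sequence` plugs in, so a full Spanish tagger can back the
pipeline.  The shipped engine is a deterministic dictionary tagger over a
packaged ~190-word Spanish list (personal pronouns carry person/number);
unknown words are tagged `other` and counted, so tagging coverage is always
reportable.  Hashtag tokens are not drug-matchable by default (the lexicon
matcher operates on word tokens; `match_hashtags=True` opts in), and
accent-insensitive drug matching is off by default because the packaged
name list is accent-free.

The emotion and sentiment word lists packaged under `data/` are *synthetic*
stand-ins built for this package (the reference lexicons they emulate are
not redistributable): small, disjoint Spanish word lists per category.  The
negation list (`no, nada, nadie, nunca, jamás, ni, tampoco, sin, ninguno,
ninguna`) is the package default and extendable; multi-word negation
expressions are supported by the lexicon reader.

## Paired statistics

For each feature, per-user differences d = (in − unknown) give
`t = d̄/(s_d/√n)` with the n−1 SD and a two-sided p from Student's t with
df = n − 1.  Benjamini–Hochberg step-up adjustment is applied across all
features of one comparison run (~29 tests); both raw and adjusted p are
reported so either reading of "corrected" is inspectable.  Features with
fewer than two complete pairs or zero difference variance are flagged
(`insufficient_n`, `degenerate_variance`) and excluded from the BH family
rather than silently skipped.  Report tables round means/SDs/t to two
decimals.

Inter-rater utilities: percent agreement and Cohen's
κ = (Po − Pe)/(1 − Pe) with Pe from marginal products; κ is NaN when both
raters are constant and identical (Pe = 1).

## Synthetic cohort calibration

Each user carries latent per-period parameters drawn from a Gaussian copula
with per-period marginals (gamma for rates and word counts, beta for
probabilities and shares):

* The cross-period correlation is derived from the calibration triple
  (s_in, s_unk, sd_diff) as ρ = (s_in² + s_unk² − sd_diff²)/(2·s_in·s_unk),
  so the planted per-user differences have exactly the intended SD —
  e.g. tweet rates 11.44 vs 9.07/day (SDs 10.05/7.21) with sd_diff 9.72
  give ρ ≈ 0.40.
* Where only an sd_diff is known (POS, pronoun and emotion rows), the
  marginal SD is set equal to sd_diff with ρ = 0.5, which reproduces that
  sd_diff exactly.
* Weekday/weekend rates derive from the overall rate and a latent weekday
  share p_wd: weekday rate = r·1.4·p_wd, weekend rate = r·3.5·(1 − p_wd),
  so the weekly total is conserved at 7r.
* Pronoun person/number shares and POS category shares are drawn per slot
  and normalized per draw; normalization rescales the means by the
  reciprocal of their sum (the six pronoun means sum to ~0.965, so the
  planted first-person-singular share is ~0.513/0.495 after normalization
  while its difference scale is preserved).
* Tweet text is token soup: a word budget ~1 + Poisson(w − 1) filled with
  planted lexicon-indicator words, function words (a configurable 20% share
  of determiners/adpositions/conjunctions that exercises the POS
  denominator exclusion), and content words drawn from the POS mixture;
  links and @mentions are appended by per-user Bernoulli probabilities.
  Background pools exclude all lexicon and drug-name words, so indicators
  are planted exactly.  Lexicon-insert words are tagged `other` by the
  dictionary tagger, which dilutes the five reported POS shares by the
  insert fraction (~7%); this is a known, period-stable offset.
* Anchor days always contain at least one tweet, whose text embeds the drug
  name; mention events are emitted with `intake_confirmed = True`.
  Retweet traffic is generated at rate·rf/(1−rf) (default rf = 0.2788) and
  flagged.
* Day labels at generation time follow the same window rule the labeling
  stage applies, so planted-vs-recovered label agreement is exactly 100%
  under matched configs — a property test, and a negative control with a
  mismatched washout shows off-diagonal confusion mass.

Everything is deterministic given one seed (`numpy.random.default_rng`).

### What the generator does not emulate

Natural language (features are lexicon/indicator-based, so realism is
unnecessary for testability); topic or time-of-year structure; per-tweet
offset changes (one fixed offset per user, matching the one-time time-zone
adjustment of the design); the free-text nuances of intake curation.
Passing tests therefore validate the *pipeline machinery and statistics*,
not the linguistic validity of any lexicon.

## Problem sizes and replicate studies

Replicate studies use a compact geometry chosen for a single-CPU budget: a
fixed ~4.2-month span per user with the anchor near the span start (31
in-treatment days, a 60-day washout zone, ≥35 unknown days) and no retweet
traffic.  The type-I calibration study runs 200 null cohorts of 50 users at
a quieter 3 tweets/day (the paired t's size does not depend on tweet volume
once the minimum-tweets rule is satisfiable); the effect-recovery study
runs 60 calibrated cohorts of 187 users.  The acceptance script runs one
calibrated 187-user cohort.

## Known limitations

* **Power of the calibrated contrasts.** Under the calibrated effect sizes,
  the per-test power of the daytime (t ≈ 2.9) and first-person-singular
  (t ≈ 2.7) contrasts at a BH-adjusted 0.05 across the 29-feature family is
  ~0.73 and ~0.64 *even with zero measurement noise*; measured detection
  rates over 60 replicates are ~0.83 (tweets/day), ~0.53 (daytime) and
  ~0.67 (first-person singular).  A detection requirement of ≥80% for all
  three is therefore not attainable at these effect sizes, and the
  corresponding acceptance test documents the shortfall.
* **Selection truncation.** The minimum-tweets rule truncates the low-rate
  tail of the cohort: with the rate marginals planted pre-selection, the
  post-selection mean tweets/day difference is ~2.6–2.7 rather than the
  planted 2.37.  The pipeline measures without bias for the users it
  includes (tested); the gap is a property of the design, not of the
  implementation.
* Several reported table rows are internally inconsistent (recomputing t
  from their own mean/SD gives 3.21 vs 3.15 for verbs, 2.92 vs 3.07 for the
  daytime share); the package reports recomputed values and the deltas
  rather than forcing agreement.
* The packaged frequency table of drug-name mentions keeps its 32 printed
  rows although the accompanying text speaks of 33 distinct words; the
  discrepancy is preserved, not resolved.
* Whether emotion percentages are tweet-level indicators or word-level
  shares is a design ambiguity; the indicator reading is the default and
  the manifest records which was used.
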