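# Methods

## The classification model

`fallfinder` treats fall identification as note-level phenotyping: the unit
of analysis is one ED provider note, and the target is whether the note
documents a fall — in the WHO sense of an event whereby a person
unexpectedly comes to rest on the ground or another lower level — related
to the current visit. The classifier is deliberately a short cascade of
deterministic rules rather than a statistical model: fall events are
documented with a small set of stock phrases, and a rules cascade is
transparent, auditable, and portable between sites without a training
corpus.

The cascade, in order, with the assumption each step encodes:

1. **Section removal.** Past Medical History and Review of Systems are cut
   before any matching. Assumption: a fall word in the PMH refers to an old
   or unrelated event, and the ROS is a telegraphic negated checklist whose
   items cannot be parsed sentence-wise. A section runs from its recognized
   header (anchored at line start or after sentence-terminal punctuation,
   case-insensitive, optional colon) to the next recognized header of any
   known type or the end of the note. Headerless notes are retained whole.
2. **Sentence division.** Rule-based splitting at `.`, `!`, `?` and newline
   runs, guarded by a configurable abbreviation list (Dr., Mr., Ms., Mrs.,
   pt., vs., approx., e.g., i.e.) and a no-split rule inside decimal
   numbers. A deterministic splitter keeps every downstream test exact; a
   learned splitter would add variance without adding recall for this
   phrase-level task. Sentences never cross a retained-segment boundary,
   and all offsets are 0-based half-open positions into the original note,
   so each mention is traceable to raw text.
3. **Fall-term matching.** Case-insensitive word-boundary regex over
   fall/falls/fell/fallen/falling. Word boundaries make embedded stems
   ("fellow", "fallopian") unmatchable by construction.
4. **Exception filtering.** Five exclusion classes, applied in a fixed
   cascade order (idiom → uncertainty → averted → risk → season), each a
   list of case-insensitive patterns matched against the whole sentence; a
   pattern excludes a candidate when its match span covers the term, which
   lets a cue sit far from the term ("uncertain if the patient ... fell").
   Certainty phrases used for medical decision making ("presumed fall",
   "believed to have fallen") are deliberately absent from every exception
   list and therefore survive to negation.
5. **Directional negation.** A surviving candidate is NEGATED iff a cue
   token ("no", "not", "n't", "negative", "never", "didn't", "without",
   "denies", "deny") occurs as a whole token — "n't" also as a token
   suffix, with straight and curly apostrophes equivalent — anywhere before
   the term in its sentence. Cues after the term are ignored: post-term
   negation overwhelmingly targets events that did not occur *during* the
   fall ("fell but did not lose consciousness"). Scope is the entire
   preceding portion of the sentence, with no token-distance window, and
   each mention is tested independently, so one "denies" negates every
   fall term that follows it in the sentence.
6. **Note-level vote.** FALL iff positive mentions strictly outnumber
   negated mentions; excluded mentions carry no vote; an empty mention set
   is NO_FALL. The tie-break is negation-favoring by default because the
   positive-favoring alternative trades many false positives for few false
   negatives; both variants are exposed (`aggregation.tie_break`) so that
   trade-off is measurable on adversarial corpora.

## Rulesets and the one documented contradiction

All knobs live in YAML (`rulesets/published.yaml`, `rulesets/extended.yaml`).
The published exception lists are seeds, not a closed vocabulary: the
original lists grew iteratively against a development corpus that cannot be
shared, so the default ruleset ships exactly the documented phrases and the
YAML is the extension point. The `extended` ruleset adds only the error
sources documented as fixable: the FOOSH acronym as a fall term, the
"fell/fall apart" idiom, season without "of" ("fall 2016"), "unable to
confirm … fall" as uncertainty, and the "PMH:" header abbreviation.

One documented behavior is internally contradictory: "Negative for falls"
is reported as a false positive even though "negative" is in the cue list.
The single mechanical explanation is case-sensitive cue matching missing
the sentence-initial capital. Rather than silently resolving this, the
`negation.case_sensitive` flag makes both behaviors reachable: the default
(insensitive) negates the sentence; the case-sensitive setting reproduces
the reported false positive. The regression suite exercises both and keeps
this fixture out of the published-behavior corpus constructs.

## Evaluation statistics

Verdicts are scored against gold labels note-by-note; notes whose only
mentions are negated count as no-fall on both sides. Point estimates are
the standard 2×2 ratios; any metric with a zero denominator is reported as
explicitly undefined, never as 0 or 1. Interval estimates default to the
exact Clopper–Pearson interval, computed from beta quantiles
(lower = B(α/2; k, n−k+1), upper = B(1−α/2; k+1, n−k)), with the boundary
cases pinned to exactly 0 and 1. Clopper–Pearson was chosen as the default
because it is exact (guaranteed coverage) and reproduces the reference
intervals for sensitivity, specificity and accuracy at printed precision;
a Wilson score interval is available via `ci_method="wilson"`. Cohen's κ on
a 2×2 agreement table is provided as (p_o − p_e)/(1 − p_e) with chance
agreement from marginal products; its standard error is deliberately not
computed, since there are several inequivalent formula variants and no
basis for picking one. Display rounding follows the field's convention:
percentages to one decimal, F1 to three.

## The synthetic note generator

Real ED notes are PHI and cannot ship, so the generator emulates what the
pipeline actually consumes: sectioned structure (Chief Complaint, HPI,
Past Medical History, Review of Systems, Physical Exam, MDM) and fall
phraseology, embedded in minimal clinical filler. Each note carries exactly
one construct from a family with a known gold label and a known expected
verdict under the published ruleset:

* a **benign pool** (clean positives, post-term-negation positives,
  certainty phrases, negations, idiom/uncertainty/averted/risk/season
  exclusions, embedded words, historical falls confined to the PMH) on
  which the published ruleset is correct by construction — so an
  adversarial-free corpus must score 100% sensitivity and specificity, and
  any failure is a pipeline regression, not noise;
* an **adversarial pool** reproducing the documented error families, whose
  gold label and expected published verdict disagree by construction
  (chief-complaint errors, objects that fell, historical falls narrated in
  the HPI, "fall 2016", the "PMH:" header, transcription errors, "fell
  apart", "unable to confirm", FOOSH, falls described without fall words,
  and a relevant fall recorded only in the PMH).

Defaults mirror the validation study's conditions: gold prevalence 0.24,
corpus size 500 for end-to-end checks. Gold-positive counts are assigned
exactly (round(n·prevalence), clamped by the fixed gold labels of any
adversarial draws) rather than by per-note Bernoulli draws, so small
corpora hit the target prevalence. One integer seed drives family
assignment, and each note renders from its own child stream
(`default_rng([seed, i])`), making corpora byte-identical across runs and
stable under partial regeneration.

What passing on synthetic corpora shows — and what it does not: it
establishes that the implementation realizes the stated rules exactly
(every construct routes through the intended rule) and that the documented
error taxonomy is faithfully reproduced. It does not establish real-world
operating characteristics: real notes carry typographical errors, dictation
artifacts, site-specific header dialects and fall descriptions with no fall
words, at frequencies a template generator cannot estimate. The quoted
sensitivity/specificity of the approach on real notes comes from the
validation study's printed 2×2 outcome, which the evaluation module
recomputes; it is not re-derivable from synthetic text.

## Numerical and degenerate-input choices

* Offsets: 0-based half-open everywhere; slicing the original text by any
  sentence's or mention's offsets reproduces it exactly.
* Overlapping fall matches resolve left-to-right (regex scan order);
  overlapping section headers resolve leftmost-first, longest-at-position.
* Empty or whitespace-only notes flow through the whole pipeline and
  classify NO_FALL; they are never rejected.
* Note text is read as UTF-8 with a latin-1 fallback, since EHR exports
  mix encodings.
* An all-zero confusion matrix and an empty agreement table are fatal
  errors, not silent zeros.

## Known limitations

* The exception vocabulary is a seed list; recall on a new site's notes
  depends on extending the YAML against local phrasing.
* Section handling presumes recognizable textual headers; notes from
  systems with different header dialects need the `sections` lists adapted.
* Falls described entirely without fall-family words, and transcription
  errors, are out of reach of this rules cascade by design.
* Only note-level classification is provided; fusing multiple notes per
  encounter is out of scope.
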