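# Default ruleset: reproduces the published behavior of the pragmatic
# fall-identification algorithm, including its documented blind spots
# (e.g. "fall 2016" without "of", the idiom "fell apart", FOOSH).
fall_pattern: '\b(?:fall|falls|fell|fallen|falling)\b'

exceptions:
  exception:
    - '\b(?:fell|fall|falls|falling)\s+asleep\b'
  uncertain:
    - '\bmay\s+have\s+fallen\b'
    - '\b(?:uncertain|unsure)\s+(?:if|whether)\b[^.!?]*?\b(?:fall|falls|fell|fallen|falling)\b'
  averted:
    - '\b(?:almost|nearly)\s+(?:fell|fall|falls|fallen|falling)\b'
  risk:
    - '\bfall\s+risks?\b'
    - '\brisk\s+of\s+fall(?:s|ing)?\b'
    - '\bfall\s+precautions?\b'
  season:
    - '\bfall\s+of\s+(?:19|20)\d{2}\b'

# Certainty language that must NOT be excluded; listed for documentation and
# regression cover — these phrases match no exception pattern.
keep_phrases:
  - presumed fall
  - believed to have fallen

negation:
  cues: ["no", "not", "n't", "negative", "never", "didn't", "without", "denies", "deny"]
  case_sensitive: false

aggregation:
  tie_break: negated_wins

sections:
  remove:
    - Past Medical History
    - Review of Systems
  known:
    - Chief Complaint
    - History of Present Illness
    - HPI
    - Past Medical History
    - Review of Systems
    - Physical Exam
    - Medical Decision Making
    - MDM
    - Assessment
    - Plan
    - ED Course
    - Medications
    - Allergies
    - Social History
    - Family History

sentences:
  abbreviations: [dr, mr, ms, mrs, pt, vs, approx, e.g, i.e]
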