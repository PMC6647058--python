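# Extended ruleset: the published rules plus the fixable error sources the
# validation study itself identified — the FOOSH acronym, the idiom
# "fell/fall apart", season written without "of" ("fall 2016"),
# "unable to confirm ... fall", and the "PMH:" header abbreviation.
fall_pattern: '\b(?:fall|falls|fell|fallen|falling|foosh)\b'

exceptions:
  exception:
    - '\b(?:fell|fall|falls|falling)\s+asleep\b'
    - '\b(?:fell|fall|falls|falling)\s+apart\b'
  uncertain:
    - '\bmay\s+have\s+fallen\b'
    - '\b(?:uncertain|unsure)\s+(?:if|whether)\b[^.!?]*?\b(?:fall|falls|fell|fallen|falling)\b'
    - '\bunable\s+to\s+confirm\b[^.!?]*?\b(?:fall|falls|fell|fallen|falling)\b'
  averted:
    - '\b(?:almost|nearly)\s+(?:fell|fall|falls|fallen|falling)\b'
  risk:
    - '\bfall\s+risks?\b'
    - '\brisk\s+of\s+fall(?:s|ing)?\b'
    - '\bfall\s+precautions?\b'
  season:
    - '\bfall\s+(?:of\s+)?(?:19|20)\d{2}\b'

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
    - PMH
  known:
    - Chief Complaint
    - History of Present Illness
    - HPI
    - Past Medical History
    - PMH
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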