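"""Detect subcategory mentions, with negation handling, in two short notes.

The matcher finds lexicon terms in preprocessed note text and flags mentions
governed by a negation trigger; terms that begin with a negation token
("no contact from family") carry their negation as part of their meaning and
are never suppressed.
"""

from ineads import Note, annotate_note, seed_default_lexicon

lexicon = seed_default_lexicon()

notes = [
    Note("n1", "p1", "h1", "nursing", None,
         "social history: works as police officer lives alone never married "
         "no children"),
    Note("n2", "p1", "h1", "social work", None,
         "denies lives alone. social dispo full code no contact from family"),
]

for note in notes:
    annotation = annotate_note(note, lexicon)
    print(f"note {note.note_id}: {note.text!r}")
    for mention in annotation.mentions:
        flag = "NEGATED" if mention.negated else "asserted"
        print(f"  {mention.subcategory:24s} {mention.term!r:28s} {flag}")
    print(f"  -> subcategories present: {sorted(annotation.subcategories_present)}")
    print()

print("A note's 'subcategories present' are the non-negated mentions; these")
print("are what roll up into the admission-level cohort rules.")
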