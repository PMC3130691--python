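"""Published summary-table constants used to build deterministic fixture
corpora: the relation-type distribution, the per-sense distribution split
by relation type (single- and multi-sense rows), the contextual-ambiguity
inventory of explicit connectives, and the sense-by-segment counts.

Two rows of the sense-by-segment table are internally inconsistent as
published (cells of the Conjunction row sum to 749 against a printed row
total of 754; Temporal cells sum to 374 against 515). The printed cells
are kept verbatim and the printed totals carried separately in
``TABLE12_PRINTED_TOTALS`` so downstream code can flag, not repair, the
discrepancy.
"""

from __future__ import annotations

# rel_type -> (tokens, unique expression types); NoRel has no types.
RELATION_TYPE_TABLE: dict[str, tuple[int, int]] = {
    "Explicit": (2636, 179),
    "Implicit": (3001, 57),
    "AltLex": (193, 165),
    "NoRel": (29, 0),
}

# sense type -> (explicit, implicit, altlex) counts, single-sense rows.
SENSE_TABLE_SINGLE: dict[str, tuple[int, int, int]] = {
    "Alternative": (31, 3, 3),
    "Background": (0, 132, 1),
    "Cause": (339, 98, 105),
    "Circumstance": (8, 221, 1),
    "Concession": (257, 70, 2),
    "Condition": (22, 0, 0),
    "Conjunction": (421, 641, 3),
    "Continuation": (24, 831, 0),
    "Contrast": (205, 75, 2),
    "Exception": (7, 2, 0),
    "Instantiation": (21, 53, 14),
    "Purpose": (616, 0, 1),
    "Reinforcement": (22, 60, 19),
    "Restatement": (69, 445, 19),
    "Similarity": (5, 0, 0),
    "Temporal": (394, 370, 16),
}

# (sense1, sense2) -> (explicit, altlex) counts; implicits never carry two.
SENSE_TABLE_MULTI: dict[tuple[str, str], tuple[int, int]] = {
    ("Cause", "Background"): (8, 0),
    ("Cause", "Conjunction"): (5, 0),
    ("Cause", "Reinforcement"): (0, 1),
    ("Cause", "Temporal"): (6, 3),
    ("Concession", "Background"): (2, 0),
    ("Concession", "Circumstance"): (1, 0),
    ("Condition", "Circumstance"): (2, 0),
    ("Condition", "Temporal"): (5, 0),
    ("Conjunction", "Temporal"): (70, 1),
    ("Continuation", "Reinforcement"): (1, 0),
    ("Contrast", "Background"): (0, 1),
    ("Contrast", "Concession"): (1, 0),
    ("Purpose", "Conjunction"): (1, 0),
    ("Reinforcement", "Conjunction"): (0, 1),
    ("Temporal", "Circumstance"): (92, 0),
    ("Temporal", "Continuation"): (1, 0),
}

# connective -> (type-level first senses observed, token count).
AMBIGUITY_TABLE: dict[str, tuple[tuple[str, ...], int]] = {
    "accordingly": (("Cause", "Conjunction"), 2),
    "although": (("Concession", "Contrast"), 76),
    "and": (
        ("Cause", "Concession", "Conjunction", "Continuation", "Purpose", "Temporal"),
        274,
    ),
    "as": (("Cause", "Purpose", "Temporal"), 23),
    "both upon": (("Circumstance", "Temporal"), 2),
    "but": (("Concession", "Contrast"), 42),
    "by": (("Cause", "Purpose", "Temporal"), 262),
    "finally": (("Conjunction", "Temporal"), 21),
    "however": (("Concession", "Contrast"), 117),
    "in part by": (("Cause", "Purpose"), 3),
    "in particular": (("Instantiation", "Restatement"), 4),
    "in response to": (("Cause", "Circumstance", "Temporal"), 12),
    "in turn": (("Cause", "Conjunction", "Temporal"), 6),
    "in": (("Circumstance", "Purpose"), 3),
    "indeed": (("Circumstance", "Reinforcement"), 15),
    "on the other hand": (("Concession", "Contrast"), 6),
    "once": (("Circumstance", "Temporal"), 7),
    "second": (("Conjunction", "Temporal"), 3),
    "since": (("Cause", "Temporal"), 52),
    "so": (("Cause", "Restatement"), 7),
    "then": (("Restatement", "Temporal"), 91),
    "therefore": (("Cause", "Restatement"), 75),
    "thus": (("Cause", "Restatement"), 77),
    "upon": (("Circumstance", "Temporal"), 15),
    "when": (("Circumstance", "Condition", "Temporal"), 65),
    "while": (("Concession", "Conjunction", "Contrast", "Temporal"), 64),
    "whilst": (("Concession", "Contrast"), 4),
}

# sense type -> counts per (Introduction, Methods, Results, Abstract,
# Discussion) segment, published cells.
IMRAD_TABLE: dict[str, tuple[int, int, int, int, int]] = {
    "Alternative": (4, 3, 7, 0, 15),
    "Background": (24, 7, 36, 15, 39),
    "Cause": (80, 16, 134, 33, 208),
    "Circumstance": (11, 7, 112, 13, 13),
    "Concession": (59, 3, 73, 21, 116),
    "Condition": (1, 6, 0, 1, 11),
    "Conjunction": (105, 100, 271, 78, 195),
    "Continuation": (80, 121, 112, 17, 85),
    "Contrast": (26, 9, 118, 12, 81),
    "Exception": (1, 2, 2, 0, 1),
    "Instantiation": (17, 0, 9, 3, 42),
    "Purpose": (93, 84, 144, 35, 104),
    "Reinforcement": (14, 3, 14, 4, 50),
    "Restatement": (63, 47, 124, 29, 65),
    "Similarity": (0, 0, 2, 0, 3),
    "Temporal": (41, 259, 0, 22, 52),
}

# Published row totals, kept for flagging (two disagree with the cells).
TABLE12_PRINTED_TOTALS: dict[str, int] = {
    "Alternative": 29,
    "Background": 121,
    "Cause": 471,
    "Circumstance": 156,
    "Concession": 272,
    "Condition": 19,
    "Conjunction": 754,
    "Continuation": 415,
    "Contrast": 246,
    "Exception": 6,
    "Instantiation": 71,
    "Purpose": 460,
    "Reinforcement": 85,
    "Restatement": 328,
    "Similarity": 5,
    "Temporal": 515,
}
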