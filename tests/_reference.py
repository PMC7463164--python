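"""Printed difference columns of the bundled reference optode tables.

Per optode id: (dx, dy, dz, d) as printed in the source report, used as
frozen expected values for the displacement metric.
"""

ADULT_PRINTED_DIFFERENCES = {
    "1":  (2, 5, 2, 5.7),
    "2":  (1, 5, 2, 5.5),
    "3":  (3, 7, 2, 7.9),
    "4":  (5, 7, 3, 9.1),
    "5":  (1, 0, 3, 3.2),
    "6":  (1, 2, 5, 5.5),
    "7":  (0, 0, 2, 2.0),
    "8":  (1, 5, 0, 5.1),
    "9":  (1, 1, 2, 2.4),
    "10": (3, 11, 1, 11.4),
    "11": (1, 2, 2, 3.0),
    "12": (0, 12, 2, 12.2),
    "13": (3, 5, 1, 5.9),
    "14": (4, 11, 4, 12.4),
    "15": (4, 4, 1, 5.7),
    "16": (5, 8, 2, 9.6),
    "17": (4, 3, 8, 9.4),
    "18": (1, 2, 5, 5.5),
}

CHILD_PRINTED_DIFFERENCES = {
    "1":  (0, 2, 0, 2.0),
    "2":  (0, 2, 3, 3.6),
    "3":  (2, 4, 7, 8.3),
    "4":  (3, 3, 10, 10.9),
    "5":  (3, 2, 9, 9.7),
    "6":  (3, 2, 16, 16.4),
    "7":  (2, 5, 0, 5.4),
    "8":  (1, 2, 4, 4.6),
    "9":  (1, 5, 3, 5.9),
    "10": (1, 3, 1, 3.3),
    "11": (0, 0, 4, 4.0),
    "12": (1, 7, 2, 7.3),
    "13": (3, 3, 9, 9.9),
    "14": (3, 6, 4, 7.8),
    "15": (1, 1, 10, 10.1),
    "16": (2, 1, 3, 3.7),
    "17": (5, 4, 12, 13.6),
    "18": (2, 2, 12, 12.3),
}
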