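"""Published deployment windows of the CNP blue whale tagging program.

Transmission start/end dates and reported track durations (days) for the
ten blue whales satellite-tagged off Chilean Northern Patagonia in
2013–2016 (whale #2's track is split at a month-long transmission gap
into segments 2a/2b).  These printed dates are the reference inputs for
the inclusive day-count convention used throughout the package.
"""

from __future__ import annotations

from datetime import date

#: track_id -> (tag type, transmission start, transmission end,
#:              reported duration in days)
DEPLOYMENTS: dict[str, tuple[str, date, date, int]] = {
    "1":  ("Spot", date(2013, 4, 1),  date(2013, 5, 15),  45),
    "2a": ("Spot", date(2015, 4, 9),  date(2015, 4, 25),  17),
    "2b": ("Spot", date(2015, 5, 31), date(2015, 7, 6),   37),
    "3":  ("Spot", date(2015, 4, 14), date(2015, 7, 5),   83),
    "4":  ("MK10", date(2015, 4, 9),  date(2015, 6, 12),  65),
    "5":  ("MK10", date(2015, 4, 16), date(2015, 6, 9),   55),
    "6":  ("MK10", date(2015, 4, 17), date(2015, 9, 24), 161),
    "7":  ("MK10", date(2015, 4, 13), date(2015, 5, 3),   21),
    "8":  ("Spot", date(2016, 4, 10), date(2016, 5, 4),   25),
    "9":  ("Spot", date(2016, 4, 4),  date(2016, 4, 25),  23),
    "10": ("Spot", date(2016, 4, 5),  date(2016, 10, 22), 201),
}
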