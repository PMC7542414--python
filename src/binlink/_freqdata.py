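"""Bundled synthetic frequency tables and lexicons.

Small, self-contained stand-ins for population-level name/date-of-birth
frequency files and a national address file, which are not redistributable.
Counts follow a rough Zipf profile so that value frequencies are realistically
skewed.  Users can supply their own tables (see ``synthetic.FrequencyTable``).
"""

from __future__ import annotations

# Given names with Zipf-ish counts. (synthetic lexicon)
FIRST_NAMES: list[tuple[str, int]] = [
    ("john", 9000), ("margaret", 7200), ("david", 6100), ("susan", 5300),
    ("michael", 4700), ("jennifer", 4200), ("robert", 3800), ("linda", 3500),
    ("william", 3200), ("patricia", 3000), ("james", 2800), ("elizabeth", 2600),
    ("thomas", 2400), ("helen", 2300), ("george", 2100), ("dorothy", 2000),
    ("peter", 1900), ("kathleen", 1800), ("richard", 1700), ("shirley", 1600),
    ("kevin", 1500), ("christine", 1400), ("anthony", 1300), ("sandra", 1250),
    ("stephen", 1200), ("judith", 1150), ("mark", 1100), ("pamela", 1050),
    ("paul", 1000), ("janet", 950), ("andrew", 900), ("carol", 850),
    ("gregory", 800), ("sharon", 780), ("ian", 750), ("wendy", 720),
    ("colin", 690), ("lorraine", 660), ("neil", 630), ("glenys", 600),
    ("trevor", 570), ("maureen", 540), ("wayne", 510), ("gail", 490),
    ("scott", 460), ("kylie", 430), ("simon", 410), ("tracey", 390),
    ("nathan", 370), ("melissa", 350),
]

LAST_NAMES: list[tuple[str, int]] = [
    ("smith", 8000), ("jones", 6500), ("williams", 5400), ("brown", 4800),
    ("wilson", 4300), ("taylor", 3900), ("johnson", 3500), ("white", 3200),
    ("martin", 2900), ("anderson", 2700), ("thompson", 2500), ("nguyen", 2350),
    ("walker", 2200), ("harris", 2050), ("lewis", 1900), ("robinson", 1800),
    ("clarke", 1700), ("young", 1600), ("hall", 1500), ("wright", 1400),
    ("king", 1300), ("mitchell", 1250), ("campbell", 1200), ("ryan", 1150),
    ("stewart", 1100), ("morris", 1050), ("murphy", 1000), ("watson", 950),
    ("kelly", 900), ("singh", 860), ("murray", 820), ("phillips", 780),
    ("russell", 740), ("graham", 700), ("hunt", 660), ("palmer", 630),
    ("stone", 600), ("pearson", 570), ("fraser", 540), ("hopkins", 510),
    ("sullivan", 480), ("gordon", 450), ("novak", 420), ("kowalski", 390),
    ("pfister", 360), ("osullivan", 330), ("mcdonald", 300), ("schmidt", 270),
]

# Street-address grammar components. (synthetic lexicon)
STREET_NAMES: list[str] = [
    "kintail", "wellington", "stirling", "murray", "hampton", "victoria",
    "albany", "york", "nicholson", "ranford", "warton", "karrinyup",
    "morley", "guildford", "thornlie", "rokeby", "whitfords", "leach",
    "mounts", "orrong", "tonkin", "mitchell", "kwinana", "roe",
]

STREET_TYPES: list[str] = [
    "road", "street", "avenue", "drive", "court", "way", "crescent",
    "parade", "terrace", "loop",
]

# Alternate-name (nickname) substitutions, applied in either direction.
NICKNAMES: dict[str, str] = {
    "robert": "bob",
    "william": "bill",
    "elizabeth": "liz",
    "margaret": "peg",
    "james": "jim",
    "thomas": "tom",
    "richard": "rick",
    "michael": "mick",
    "david": "dave",
    "jennifer": "jenny",
    "patricia": "trish",
    "kathleen": "kath",
    "anthony": "tony",
    "stephen": "steve",
    "christine": "chris",
    "gregory": "greg",
    "susan": "sue",
    "dorothy": "dot",
    "pamela": "pam",
    "kevin": "kev",
}
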