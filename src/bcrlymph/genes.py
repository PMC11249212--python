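"""Bundled human IGH gene vocabularies (IMGT-style names, allele-free).

These lists cover the commonly rearranged functional IGHV/IGHD/IGHJ
segments plus the IGHV4/OR15-8 orphon, which appears in clinical
repertoires. They are the sampling vocabulary of the simulator and a
convenient reference for tests; real data may of course contain further
segments, which the feature encoder handles as out-of-vocabulary.
"""

IGHV_GENES: tuple[str, ...] = (
    "IGHV1-2", "IGHV1-3", "IGHV1-8", "IGHV1-18", "IGHV1-24", "IGHV1-45",
    "IGHV1-46", "IGHV1-58", "IGHV1-69", "IGHV2-5", "IGHV2-26", "IGHV2-70",
    "IGHV3-7", "IGHV3-9", "IGHV3-11", "IGHV3-13", "IGHV3-15", "IGHV3-20",
    "IGHV3-21", "IGHV3-23", "IGHV3-30", "IGHV3-33", "IGHV3-43", "IGHV3-48",
    "IGHV3-49", "IGHV3-53", "IGHV3-64", "IGHV3-66", "IGHV3-72", "IGHV3-73",
    "IGHV3-74", "IGHV4-4", "IGHV4-28", "IGHV4-31", "IGHV4-34", "IGHV4-39",
    "IGHV4-59", "IGHV4-61", "IGHV4/OR15-8", "IGHV5-51", "IGHV6-1",
    "IGHV7-4-1",
)

IGHD_GENES: tuple[str, ...] = (
    "IGHD1-1", "IGHD1-7", "IGHD1-26", "IGHD2-2", "IGHD2-8", "IGHD2-15",
    "IGHD2-21", "IGHD3-3", "IGHD3-9", "IGHD3-10", "IGHD3-16", "IGHD3-22",
    "IGHD4-17", "IGHD4-23", "IGHD5-12", "IGHD5-24", "IGHD6-6", "IGHD6-13",
    "IGHD6-19", "IGHD7-27",
)

IGHJ_GENES: tuple[str, ...] = (
    "IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6",
)
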