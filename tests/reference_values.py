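"""Published session summary statistics of the experiment series, used
as frozen expected values by the reproduction tests.

Keys are (session_id, stage).  ``TABLE6`` holds the published strategy
estimates (alpha, gamma) at 3 decimals; ``TABLE7`` the signed tolerance
distances to the equilibrium curve at their published precision;
``TABLE8`` the percent payoff deviations at 2 decimals.  ``TABLE7_DP``
records how many decimals each distance was published with.
"""

TABLE6 = {
    ("15.09.2015", "before"): (0.104, 0.226),
    ("21.09.2015", "before"): (0.139, 0.105),
    ("28.09.2015", "before"): (0.329, 0.500),
    ("05.10.2015", "before"): (0.228, 0.143),
    ("09.10.2015", "before"): (0.286, 0.419),
    ("12.10.2015", "before"): (0.368, 0.481),
    ("19.10.2015", "before"): (0.260, 0.465),
    ("26.10.2015", "before"): (0.160, 0.346),
    ("15.09.2015", "after"): (0.462, 0.871),
    ("21.09.2015", "after"): (0.395, 0.736),
    ("28.09.2015", "after"): (0.411, 0.763),
    ("05.10.2015", "after"): (0.329, 0.756),
    ("09.10.2015", "after"): (0.358, 0.670),
    ("12.10.2015", "after"): (0.439, 0.816),
    ("19.10.2015", "after"): (0.650, 0.855),
    ("26.10.2015", "after"): (0.239, 0.813),
}

TABLE7 = {
    ("15.09.2015", "before"): 0.03269024,
    ("21.09.2015", "before"): 0.14237892,
    ("28.09.2015", "before"): 0.11205629,
    ("05.10.2015", "before"): 0.20802336,
    ("09.10.2015", "before"): 0.10754084,
    ("12.10.2015", "before"): 0.1597411,
    ("19.10.2015", "before"): 0.05905651,
    ("26.10.2015", "before"): 0.01923364,
    ("15.09.2015", "after"): 0.185075,
    ("21.09.2015", "after"): 0.106521,
    ("28.09.2015", "after"): 0.119693,
    ("05.10.2015", "after"): 0.038593,
    ("09.10.2015", "after"): 0.081434,
    ("12.10.2015", "after"): 0.148679,
    ("19.10.2015", "after"): 0.367935,
    ("26.10.2015", "after"): -0.0512,
}

TABLE7_DP = {
    ("15.09.2015", "before"): 8,
    ("21.09.2015", "before"): 8,
    ("28.09.2015", "before"): 8,
    ("05.10.2015", "before"): 8,
    ("09.10.2015", "before"): 8,
    ("12.10.2015", "before"): 7,
    ("19.10.2015", "before"): 8,
    ("26.10.2015", "before"): 8,
    ("15.09.2015", "after"): 6,
    ("21.09.2015", "after"): 6,
    ("28.09.2015", "after"): 6,
    ("05.10.2015", "after"): 6,
    ("09.10.2015", "after"): 6,
    ("12.10.2015", "after"): 6,
    ("19.10.2015", "after"): 6,
    ("26.10.2015", "after"): 4,
}

TABLE8 = {
    ("15.09.2015", "before"): 0.03,
    ("21.09.2015", "before"): 0.92,
    ("28.09.2015", "before"): 0.25,
    ("05.10.2015", "before"): 1.68,
    ("09.10.2015", "before"): 0.26,
    ("12.10.2015", "before"): 0.51,
    ("19.10.2015", "before"): 0.08,
    ("26.10.2015", "before"): 0.01,
    ("15.09.2015", "after"): 0.31,
    ("21.09.2015", "after"): 0.16,
    ("28.09.2015", "after"): 0.19,
    ("05.10.2015", "after"): 0.02,
    ("09.10.2015", "after"): 0.11,
    ("12.10.2015", "after"): 0.25,
    ("19.10.2015", "after"): 1.01,
    ("26.10.2015", "after"): 0.04,
}

# The six session stages published as consistent with the equilibrium
# curve (|distance| < 0.1).
WITHIN_THRESHOLD = {
    ("15.09.2015", "before"),
    ("19.10.2015", "before"),
    ("26.10.2015", "before"),
    ("05.10.2015", "after"),
    ("09.10.2015", "after"),
    ("26.10.2015", "after"),
}
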