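"""Published per-web SEA values of the six removal strategies (threshold
0.5, 10 replicates averaged, 12 estuarine/wetland carbon-flux webs),
embedded for regression tests of the comparison statistics."""

SEA_BY_METHOD = {
    "OD": [0.374, 0.267, 0.246, 0.149, 0.281, 0.283, 0.279, 0.378, 0.297, 0.294, 0.326, 0.307],
    "ID": [0.322, 0.283, 0.274, 0.200, 0.249, 0.243, 0.265, 0.301, 0.304, 0.248, 0.317, 0.287],
    "SD": [0.315, 0.272, 0.281, 0.190, 0.272, 0.260, 0.300, 0.364, 0.301, 0.294, 0.336, 0.309],
    "PD": [0.376, 0.291, 0.262, 0.171, 0.281, 0.267, 0.272, 0.327, 0.315, 0.263, 0.327, 0.306],
    "EIG": [0.302, 0.130, 0.179, 0.082, 0.217, 0.193, 0.233, 0.348, 0.281, 0.217, 0.274, 0.223],
    "TS": [0.415, 0.363, 0.361, 0.320, 0.373, 0.359, 0.398, 0.420, 0.410, 0.393, 0.415, 0.391],
}

#: (S, C_n, printed C) rows of the published web-characteristics table
#: for which all three numbers appear.
CONNECTANCE_ROWS = [
    (21, 61, 0.138),
    (25, 104, 0.166),
    (30, 77, 0.086),
    (31, 332, 0.345),
    (125, 1969, 0.126),
]
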