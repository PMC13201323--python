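"""Shared study configuration for the example scripts."""

from ecoseasons import RegimeSpec


def two_season_regimes():
    """Two behavioral regimes with a 3:1 step-scale ratio and distinct
    habitat preferences, switching at ordinal days 100 and 300."""
    return [
        RegimeSpec(
            "summer", start_day=100, end_day=299,
            step_scale=300.0, step_shape=2.0, angular_concentration=0.5,
            habitat_weights={"wetland": 1.5, "deciduous_forest": 0.8},
        ),
        RegimeSpec(
            "winter", start_day=300, end_day=99,
            step_scale=100.0, step_shape=2.0, angular_concentration=0.5,
            habitat_weights={"coniferous_forest": 1.5, "shrubland": 0.8},
        ),
    ]
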