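# Calibration groups for the ratio models, and the default estimate plan.
# "members: all" means every specimen in the calibration table that carries
# the proxy in question. Edit this file (or pass --groups) to change which
# extant specimens calibrate each comparison set.
groups:
  all_varanus:
    members: all
  komodoensis:
    members: ["AMNH R 37908", "AMNH R 37909"]
  indo_asian_a:
    members:
      - "AMNH R 29932"
      - "AMNH R 118713"
      - "AMNH R 77646"
      - "UF 64743"
      - "AMNH R 141071"
      - "AMNH R 49230"
  vko_vgo:
    members: ["AMNH R 37908", "AMNH R 37909", "AMNH R 82819"]

# One estimate per row: fossil (by report label + proxy) x calibration group.
estimates:
  - {label: "Saniwa ensidens", group: all_varanus, proxy: DVL}
  - {label: "V. amnhophilis", group: all_varanus, proxy: BCL}
  - {label: "V. amnhophilis", group: indo_asian_a, proxy: BCL}
  - {label: "V. amnhophilis", group: all_varanus, proxy: DVL}
  - {label: "V. amnhophilis", group: indo_asian_a, proxy: DVL}
  - {label: "V. priscus A", group: all_varanus, proxy: BCL}
  - {label: "V. priscus A", group: vko_vgo, proxy: BCL}
  - {label: "V. priscus A", group: komodoensis, proxy: BCL}
  - {label: "V. priscus B", group: all_varanus, proxy: DVL}
  - {label: "V. priscus B", group: vko_vgo, proxy: DVL}
  - {label: "V. priscus B", group: komodoensis, proxy: DVL}
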