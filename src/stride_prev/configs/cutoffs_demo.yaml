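version: demo-0.1
source: Synthetic demo screening cut-offs; NOT the published DSRS / Brief CSI-D cut
  points, which are not redistributed here.
cutoffs:
  dsrs:
    clauses:
    - - - dsrs
        - ge
        - 18
    source: 'demo: DSRS total >= 18 screens positive'
  brief_csid:
    clauses:
    - - - cogscore
        - le
        - 4
    - - - cogscore
        - le
        - 6
      - - relscore
        - ge
        - 3
    source: 'demo two-threshold rule: low cognition alone, or borderline cognition
      with informant-reported impairment'
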