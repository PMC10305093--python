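version: demo-0.1
source: Synthetic demo item inventories for the scoring engine; NOT the published
  instrument item sets, which are not redistributed here.
missing_codes:
- 901
- 902
- 903
instruments:
  csid_cog:
    max_missing_allowed: 0
    max_score: 9
    items:
    - item_id: csid_cog_q01
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q02
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q03
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q04
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q05
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q06
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q07
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q08
      codes:
        0: 0
        1: 1
    - item_id: csid_cog_q09
      codes:
        0: 0
        1: 1
  csid_inf:
    max_missing_allowed: 0
    max_score: 6
    items:
    - item_id: csid_inf_q01
      codes:
        0: 0
        1: 1
    - item_id: csid_inf_q02
      codes:
        0: 0
        1: 1
    - item_id: csid_inf_q03
      codes:
        0: 0
        1: 1
    - item_id: csid_inf_q04
      codes:
        0: 0
        1: 1
    - item_id: csid_inf_q05
      codes:
        0: 0
        1: 1
    - item_id: csid_inf_q06
      codes:
        0: 0
        1: 1
  cerad:
    max_missing_allowed: 0
    max_score: 10
    items:
    - item_id: cerad_w01
      codes:
        0: 0
        1: 1
    - item_id: cerad_w02
      codes:
        0: 0
        1: 1
    - item_id: cerad_w03
      codes:
        0: 0
        1: 1
    - item_id: cerad_w04
      codes:
        0: 0
        1: 1
    - item_id: cerad_w05
      codes:
        0: 0
        1: 1
    - item_id: cerad_w06
      codes:
        0: 0
        1: 1
    - item_id: cerad_w07
      codes:
        0: 0
        1: 1
    - item_id: cerad_w08
      codes:
        0: 0
        1: 1
    - item_id: cerad_w09
      codes:
        0: 0
        1: 1
    - item_id: cerad_w10
      codes:
        0: 0
        1: 1
  eurod:
    max_missing_allowed: 0
    max_score: 12
    items:
    - item_id: eurod_q01
      codes:
        0: 0
        1: 1
    - item_id: eurod_q02
      codes:
        0: 0
        1: 1
    - item_id: eurod_q03
      codes:
        0: 0
        1: 1
    - item_id: eurod_q04
      codes:
        0: 0
        1: 1
    - item_id: eurod_q05
      codes:
        0: 0
        1: 1
    - item_id: eurod_q06
      codes:
        0: 0
        1: 1
    - item_id: eurod_q07
      codes:
        0: 0
        1: 1
    - item_id: eurod_q08
      codes:
        0: 0
        1: 1
    - item_id: eurod_q09
      codes:
        0: 0
        1: 1
    - item_id: eurod_q10
      codes:
        0: 0
        1: 1
    - item_id: eurod_q11
      codes:
        0: 0
        1: 1
    - item_id: eurod_q12
      codes:
        0: 0
        1: 1
  dsrs:
    max_missing_allowed: 0
    max_score: 54
    prorate: false
    items:
    - item_id: dsrs_memory
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
        5: 5
        6: 6
    - item_id: dsrs_speech_language
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
        5: 5
        6: 6
    - item_id: dsrs_recognition_family
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
        5: 5
    - item_id: dsrs_orientation_time
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_orientation_place
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_decisions
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_social_community
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_home_activities
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_personal_care
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_eating
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
    - item_id: dsrs_continence
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
        5: 5
    - item_id: dsrs_mobility
      codes:
        0: 0
        1: 1
        2: 2
        3: 3
        4: 4
  lawton:
    max_missing_allowed: 0
    max_score: 8
    items:
    - item_id: lawton_q01
      codes:
        0: 0
        1: 1
    - item_id: lawton_q02
      codes:
        0: 0
        1: 1
    - item_id: lawton_q03
      codes:
        0: 0
        1: 1
    - item_id: lawton_q04
      codes:
        0: 0
        1: 1
    - item_id: lawton_q05
      codes:
        0: 0
        1: 1
    - item_id: lawton_q06
      codes:
        0: 0
        1: 1
    - item_id: lawton_q07
      codes:
        0: 0
        1: 1
    - item_id: lawton_q08
      codes:
        0: 0
        1: 1
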