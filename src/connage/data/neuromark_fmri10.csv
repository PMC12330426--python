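component_id,network
SCN_01,SCN
SCN_02,SCN
SCN_03,SCN
SCN_04,SCN
SCN_05,SCN
AUD_01,AUD
AUD_02,AUD
SMN_01,SMN
SMN_02,SMN
SMN_03,SMN
SMN_04,SMN
SMN_05,SMN
SMN_06,SMN
SMN_07,SMN
SMN_08,SMN
SMN_09,SMN
VSN_01,VSN
VSN_02,VSN
VSN_03,VSN
VSN_04,VSN
VSN_05,VSN
VSN_06,VSN
VSN_07,VSN
VSN_08,VSN
VSN_09,VSN
CCN_01,CCN
CCN_02,CCN
CCN_03,CCN
CCN_04,CCN
CCN_05,CCN
CCN_06,CCN
CCN_07,CCN
CCN_08,CCN
CCN_09,CCN
CCN_10,CCN
CCN_11,CCN
CCN_12,CCN
CCN_13,CCN
CCN_14,CCN
CCN_15,CCN
CCN_16,CCN
CCN_17,CCN
DMN_01,DMN
DMN_02,DMN
DMN_03,DMN
DMN_04,DMN
DMN_05,DMN
DMN_06,DMN
DMN_07,DMN
CBN_01,CBN
CBN_02,CBN
CBN_03,CBN
CBN_04,CBN
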