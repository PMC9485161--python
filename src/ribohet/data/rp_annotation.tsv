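rp_id	universal_name	subunit	is_core
RPSA	uS2	40S	1
RPS2	uS5	40S	1
RPS3	uS3	40S	1
RPS3A	eS1	40S	1
RPS4X	eS4	40S	1
RPS5	uS7	40S	1
RPS6	eS6	40S	1
RPS7	eS7	40S	1
RPS8	eS8	40S	1
RPS9	uS4	40S	1
RPS10	eS10	40S	1
RPS11	uS17	40S	1
RPS12	eS12	40S	1
RPS13	uS15	40S	1
RPS14	uS11	40S	1
RPS15	uS19	40S	1
RPS15A	uS8	40S	1
RPS16	uS9	40S	1
RPS17	eS17	40S	1
RPS18	uS13	40S	1
RPS19	eS19	40S	1
RPS20	uS10	40S	1
RPS21	eS21	40S	1
RPS23	uS12	40S	1
RPS24	eS24	40S	1
RPS25	eS25	40S	1
RPS26	eS26	40S	1
RPS27	eS27	40S	1
RPS27A	eS31	40S	1
RPS28	eS28	40S	1
RPS29	uS14	40S	1
FAU	eS30	40S	1
RACK1	RACK1	40S	1
RPLP0	uL10	60S	1
RPLP1	P1	60S	1
RPLP2	P2	60S	1
RPL3	uL3	60S	1
RPL4	uL4	60S	1
RPL5	uL18	60S	1
RPL6	eL6	60S	1
RPL7	uL30	60S	1
RPL7A	eL8	60S	1
RPL8	uL2	60S	1
RPL9	uL6	60S	1
RPL10	uL16	60S	1
RPL10A	uL1	60S	1
RPL11	uL5	60S	1
RPL12	uL11	60S	1
RPL13	eL13	60S	1
RPL13A	uL13	60S	1
RPL14	eL14	60S	1
RPL15	eL15	60S	1
RPL17	uL22	60S	1
RPL18	eL18	60S	1
RPL18A	eL20	60S	1
RPL19	eL19	60S	1
RPL21	eL21	60S	1
RPL22	eL22	60S	1
RPL23	uL14	60S	1
RPL23A	uL23	60S	1
RPL24	eL24	60S	1
RPL26	uL24	60S	1
RPL27	eL27	60S	1
RPL27A	uL15	60S	1
RPL28	eL28	60S	1
RPL29	eL29	60S	1
RPL30	eL30	60S	1
RPL31	eL31	60S	1
RPL32	eL32	60S	1
RPL34	eL34	60S	1
RPL35	uL29	60S	1
RPL35A	eL33	60S	1
RPL36	eL36	60S	1
RPL36A	eL42	60S	1
RPL37	eL37	60S	1
RPL37A	eL43	60S	1
RPL38	eL38	60S	1
RPL39	eL39	60S	1
RPL40	eL40	60S	1
RPL41	eL41	60S	1
RPL22L1	eL22L	60S	0
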