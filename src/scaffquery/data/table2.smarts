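# Published reference queries: 18 distinct MCS patterns (element-number
# atoms, explicit bonds) behind the compounds found in both screened drug
# libraries, grouped into five named clusters.
# columns: smarts<TAB>cluster<TAB>cluster_name<TAB>hits<TAB>targets
[#6](:[#7]:[#6]:[#7]-,:[#6]-,:[#6]-[#6]-[#6]):[#6]	1	open-chain	53	PPIA_HUMAN
[#6](-,:[#6]-,:[#6]-[#6]-[#6]=[#6]-[#6])-,:[#6]-,:[#6]	1	open-chain	5	PPIA_HUMAN
[#6]:,-[#6]-,:[#7]-,:[#6]:,-[#6]:,-[#6]:,-[#6]:[#6]:[#6]	1	open-chain	1	PPIA_HUMAN
[#6]1:[#7]:[#6]:[#7]:[#6]2:[#6]:1:[#7]:[#6]:[#7]:2-[#6]1-[#8]-[#6]-[#6]-[#6]-1	2	nucleoside-analog	36	R1AB_SARS2
[#7]1:[#6]:[#7]:[#6]2:[#6]:1:[#7]:[#6]:[#7]:[#6]:2	2	nucleoside-analog	11	PPIA_HUMAN
[#6]1:[#7]:[#6]:[#7](-[#6]2-[#8]-[#6]-[#6]-[#6]-2):[#7]:1	2	nucleoside-analog	3	PPIA_HUMAN
[#6]1:[#7]:[#6]:[#7]:[#6](:[#6]:1):[#7](:[#6])-[#6]1-[#8]-[#6]-[#6]-[#6]-1	2	nucleoside-analog	2	PPIA_HUMAN
[#6]1(-[#6]2:[#6]:[#6]:[#6]3:[#6]:[#7]:[#6]:[#7]:[#7]:2:3)-[#8]-[#6]-[#6]-[#6]-1	2	nucleoside-analog	1	R1AB_SARS2
[#7]1-[#6]-[#6]-[#7]-[#6]-[#6]-1	3	miscellaneous	8	R1AB_SARS2
[#6]-:[#6]-:[#6](-[#6](=[#8])-[#7]-[#6](:-[#6]:-[#6]):-[#6]:-[#6])-:[#6]-:[#6]	3	miscellaneous	4	R1AB_SARS2
[#6]1:[#6]:[#6]:[#6]2:[#6](:[#6]:1)-[#8]-[#6]-[#8]-2	3	miscellaneous	3	R1AB_SARS2
[#6]1:[#7]:[#6]:[#6]:[#6]:[#6]:1	3	miscellaneous	3	PPIA_HUMAN
[#6](-[#6]-[#6]1-[#6]-[#6]-[#7]-[#6]-1=[#8])-[#7]-[#6](=[#8])-[#6]	3	miscellaneous	2	R1A_SARS;R1AB_SARS
[#6](-[#6]-[#6]1-[#6]-[#6]-[#7]-[#6]-1=[#8])-[#7]-[#6](=[#8])-[#6]-[#6]-[#6]1:[#6]:[#6]:[#6]:[#6]:[#6]:1	3	miscellaneous	2	R1A_SARS;R1AB_SARS
[#6](-[#7]-[#6](=[#8])-[#6]1-[#6](-[#6]-[#6]-[#7]-1-[#6](=[#8])-[#6]-[#7]-[#6]=[#8])-[#6])-[#6]-[#6](=[#8])-[#7]-[#6]1-[#6]-[#6]-1	4	cyclopropane	1	R1AB_SARS2
[#6](-[#7]-[#6](=[#8])-[#6]1-[#6]2-[#6]-[#6]-[#6]-[#6]-2-[#6]-[#7]-1)-[#6]-[#6](=[#8])-[#7]-[#6]1-[#6]-[#6]-1	4	cyclopropane	1	R1AB_SARS2
[#7]1-[#6]-[#6]2-[#6](-[#6]-1-[#6](=[#8])-[#7]-[#6]-[#6]-[#6]1-[#6]-[#6]-[#6]-1)-[#6]-2	4	cyclopropane	1	R1AB_SARS2
[#6]12-[#6]-[#6]3-[#6]-[#6](-[#6]-1)-[#6]-[#6](-[#6]-2)-[#6]-3	5	adamantane	3	PPIA_HUMAN
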