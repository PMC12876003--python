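record,code,name,parent
dimension,D1,Leisure entertainment,
dimension,D2,Health promotion,
dimension,D3,Social interaction,
dimension,D4,Self-actualization,
dimension,D5,Daily tasks,
dimension,D6,Environmental exposure,
criterion,C11,Entertainment Venues,D1
criterion,C12,Art Viewing Space,D1
criterion,C13,Historical & Cultural Sites,D1
criterion,C21,Recreation & Fitness Facilities,D2
criterion,C22,Healthcare Facilities,D2
criterion,C31,Venues for Strong Social Interaction,D3
criterion,C32,Multi-Functional Spaces,D3
criterion,C41,Intergenerational Activities,D4
criterion,C42,Skill Development,D4
criterion,C51,Ancestral Worship Sites,D5
criterion,C52,Living Convenience Facilities,D5
criterion,C53,Transportation & Mobility,D5
criterion,C54,Pet-Friendly Facilities,D5
criterion,C61,Landscape vegetation,D6
criterion,C62,Acoustic Environment Quality,D6
criterion,C63,Ambient Temperature,D6
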